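"""Generator correctness: geometry embedding, dynamics, ligand placement."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from fshrdyn.blocking import blocking_curve, plateau
from fshrdyn.contacts import frame_contacts_bruteforce
from fshrdyn.synth import (
    DynamicsParams,
    EmbeddingError,
    GroundTruth,
    StateGeometry,
    build_bundle,
    default_geometry,
    embed_geometry,
    place_ligand,
    simulate,
)
from fshrdyn.trajio import HELIX_NAMES
from tests.conftest import POCKET_RESIDUES

CA_SPACING = np.sqrt(1.5**2 + (2 * 2.3 * np.sin(np.deg2rad(50))) ** 2)


def helix_blocks(structure):
    """Atom indices per helix, in helix order."""
    return [
        np.flatnonzero(structure.helix_mask(h) & (structure.atom_names == "CA"))
        for h in HELIX_NAMES
    ]


def corresponding_atom_distances(coords, blocks, k=0):
    """Inter-helix distances between the k-th Cα of each helix.

    Helices share the same internal twist phase, so the distance between
    corresponding atoms equals the inter-axis distance exactly.
    """
    pts = np.stack([coords[b[k]] for b in blocks])
    return squareform(pdist(pts[:, :2]))


class TestBuildBundle:
    def test_heptagon_targets_realized(self, geometry, bundle):
        blocks = helix_blocks(bundle)
        realized = corresponding_atom_distances(bundle.coords, blocks)
        assert np.max(np.abs(realized - geometry.active)) < 0.1

    def test_random_embeddable_matrix_low_stress(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pts = rng.uniform(-14, 14, (7, 2))
            d = squareform(pdist(pts))
            if d[~np.eye(7, dtype=bool)].min() >= 6.0:
                break
        else:
            pytest.skip("no embeddable draw")
        geo = StateGeometry(active=d, inactive=d * 1.05)
        layouts = embed_geometry(geo)
        realized = squareform(pdist(layouts["active"]))
        assert np.linalg.norm(realized - d) / np.linalg.norm(d) < 0.05

    def test_nonembeddable_matrix_reports_stress(self):
        # a 3-D simplex-like matrix cannot live in the plane
        d = np.full((7, 7), 10.0)
        np.fill_diagonal(d, 0.0)
        geo = StateGeometry(active=d, inactive=d * 1.2)
        with pytest.raises(EmbeddingError, match="stress"):
            embed_geometry(geo)

    def test_ideal_helix_ca_spacing(self, bundle):
        for block in helix_blocks(bundle):
            spacing = np.linalg.norm(np.diff(bundle.coords[block], axis=0), axis=1)
            np.testing.assert_allclose(spacing, CA_SPACING, atol=1e-9)

    def test_short_helix_rejected(self, geometry):
        with pytest.raises(ValueError, match="at least 8"):
            build_bundle(geometry, helix_length=5)

    def test_packing_floor_enforced(self):
        d = squareform(pdist(np.random.default_rng(0).uniform(-2, 2, (7, 2))))
        with pytest.raises(ValueError, match="packing floor"):
            StateGeometry(active=d, inactive=d)

    def test_microswitch_pairs_must_differ(self, geometry):
        with pytest.raises(ValueError, match="microswitch"):
            StateGeometry(active=geometry.active, inactive=geometry.active)


class TestSimulate:
    def test_noiseless_limit_matches_active_targets(self, geometry):
        dyn = DynamicsParams(tau=5.0, sigma=1e-9, k_act_to_inact=1e-12,
                             k_inact_to_act=1e-12, dt=0.1, seed=0)
        traj, truth = simulate(geometry, dyn, 10, helix_length=8)
        blocks = helix_blocks(traj.structure)
        for f in range(traj.n_frames):
            realized = corresponding_atom_distances(traj.coords[f], blocks)
            assert np.max(np.abs(realized - geometry.active)) < 1e-6
        assert truth.occupancy["active"] == 1.0

    def test_same_seed_bit_identical(self, geometry):
        dyn = DynamicsParams(seed=42)
        t1, g1 = simulate(geometry, dyn, 200, helix_length=8)
        t2, g2 = simulate(geometry, dyn, 200, helix_length=8)
        assert np.array_equal(t1.coords, t2.coords)
        assert np.array_equal(g1.states, g2.states)

    def test_symmetric_rates_occupancy_half(self, geometry):
        dyn = DynamicsParams(tau=2.0, sigma=0.5, k_act_to_inact=0.01,
                             k_inact_to_act=0.01, dt=0.1, seed=7)
        _, truth = simulate(geometry, dyn, 50_000, helix_length=8)
        # blocking SE of the hidden-state indicator
        ind = (truth.states == "active").astype(float)
        _, se, _ = plateau(blocking_curve(ind))
        assert abs(truth.occupancy["active"] - 0.5) < 3 * se

    def test_per_state_mean_distance_near_target(self, geometry):
        dyn = DynamicsParams(tau=2.0, sigma=0.3, k_act_to_inact=0.005,
                             k_inact_to_act=0.005, dt=0.1, seed=3)
        traj, truth = simulate(geometry, dyn, 20_000, helix_length=8)
        blocks = helix_blocks(traj.structure)
        i3, i6 = 2, 5  # TMD3, TMD6
        d = np.linalg.norm(
            traj.coords[:, blocks[i6][0], :2] - traj.coords[:, blocks[i3][0], :2],
            axis=1,
        )
        for state in ("active", "inactive"):
            mask = truth.states == state
            # discard frames within 3 tau of a state change (relaxation)
            settle = int(3 * dyn.tau / dyn.dt)
            changed = np.flatnonzero(truth.states[1:] != truth.states[:-1]) + 1
            for c in changed:
                mask[c:c + settle] = False
            target = geometry.pair_target(state, "TMD6", "TMD3")
            sem = d[mask].std() / np.sqrt(mask.sum() / (2 * dyn.tau / dyn.dt))
            assert abs(d[mask].mean() - target) < 4 * sem

    def test_ground_truth_invariants(self, geometry):
        dyn = DynamicsParams(tau=2.0, sigma=0.5, k_act_to_inact=0.02,
                             k_inact_to_act=0.02, dt=0.1, seed=5)
        _, truth = simulate(geometry, dyn, 5000, helix_length=8)
        assert abs(sum(truth.occupancy.values()) - 1.0) < 1e-12
        assert truth.transition_count == int(
            np.sum(truth.states[1:] != truth.states[:-1])
        )
        assert truth.transition_count > 0

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            DynamicsParams(tau=-1.0)
        with pytest.raises(ValueError):
            DynamicsParams(dt=2.0, tau=5.0)  # dt >= tau/5
        with pytest.raises(ValueError):
            DynamicsParams(sigma=float("nan"))

    def test_ground_truth_validation(self):
        with pytest.raises(ValueError, match="sum"):
            GroundTruth(np.array(["active"]), 0, {"active": 0.5, "inactive": 0.2})


class TestPlaceLigand:
    def test_pocket_contact_set_exact(self, holo_bundle):
        lig = np.flatnonzero(holo_bundle.ligand_mask())
        prot = np.flatnonzero(holo_bundle.protein_mask())
        got = frame_contacts_bruteforce(
            holo_bundle.coords, lig, prot, holo_bundle.res_numbers, 3.5
        )
        assert got == set(POCKET_RESIDUES)

    def test_apo_passthrough(self, bundle25):
        assert place_ligand(bundle25, None) is bundle25
        assert place_ligand(bundle25, []) is bundle25

    def test_ligand_atoms_disjoint_and_flagged(self, holo_bundle, bundle25):
        assert holo_bundle.ligand_mask().sum() == len(POCKET_RESIDUES)
        assert holo_bundle.n_atoms == bundle25.n_atoms + len(POCKET_RESIDUES)
        assert not np.any(holo_bundle.ligand_mask() & holo_bundle.protein_mask())

    def test_missing_pocket_residue_errors(self, bundle25):
        with pytest.raises(KeyError, match="9999"):
            place_ligand(bundle25, [9999])

    def test_infeasible_pocket_errors(self):
        # pocket residue enclosed by a 3 Å shell of non-pocket atoms:
        # nowhere within reach is clear of the shell by cutoff + 1 Å
        from fshrdyn.synth import _fibonacci_sphere
        from fshrdyn.trajio import Structure

        shell = 3.0 * _fibonacci_sphere(100)
        n = 1 + len(shell)
        s = Structure(
            atom_names=["CA"] * n, elements=["C"] * n, res_names=["ALA"] * n,
            res_numbers=[1] + [2] * len(shell), chain_ids=["A"] * n,
            coords=np.vstack([[0.0, 0.0, 0.0], shell]),
        )
        with pytest.raises(RuntimeError, match="clearance|tight"):
            place_ligand(s, [1], contact_distance=3.4)


def test_occupancy_converges_to_rate_ratio(geometry):
    # asymmetric rates: stationary active fraction k_ia/(k_ai+k_ia) = 0.75
    dyn = DynamicsParams(tau=2.0, sigma=0.5, k_act_to_inact=0.005,
                         k_inact_to_act=0.015, dt=0.1, seed=9)
    assert dyn.stationary_active_fraction == pytest.approx(0.75)
    _, truth = simulate(geometry, dyn, 50_000, helix_length=8)
    ind = (truth.states == "active").astype(float)
    _, se, _ = plateau(blocking_curve(ind))
    assert abs(truth.occupancy["active"] - 0.75) < 3 * se
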