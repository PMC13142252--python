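"""Microswitch distances, joint projections, overlap and reference shifts."""

import numpy as np
import pytest
from scipy.stats import norm, special_ortho_group

from fshrdyn.microswitch import (
    DistancePair,
    common_grid,
    distance_distribution,
    helix_anchor,
    overlap_coefficient,
    pair_distance_series,
    project2d,
    shift_vs_reference,
)
from fshrdyn.synth import DynamicsParams, simulate
from fshrdyn.trajio import Structure, Trajectory
from tests.conftest import static_trajectory


class TestPairDistanceSeries:
    def test_pythagorean_static_pair(self):
        s = Structure(
            atom_names=["CA", "CA"], elements=["C", "C"],
            res_names=["ALA", "ALA"], res_numbers=[1, 2], chain_ids=["A", "A"],
            coords=[[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]],
        )
        pair = DistancePair("p", (1, "CA"), (2, "CA"))
        np.testing.assert_allclose(
            pair_distance_series(static_trajectory(s, 4), pair), 5.0
        )

    def test_matches_bruteforce_norm(self, bundle):
        rng = np.random.default_rng(1)
        coords = bundle.coords[None] + rng.normal(size=(20, bundle.n_atoms, 3))
        traj = Trajectory(bundle, coords, 0.1 * np.arange(20))
        pair = DistancePair.from_helices("TMD6", "TMD3")
        a, b = pair.resolve(bundle)
        series = pair_distance_series(traj, pair)
        for f in range(20):
            expected = np.sqrt(np.sum((coords[f, a] - coords[f, b]) ** 2))
            assert abs(series[f] - expected) < 1e-12

    def test_noiseless_active_geometry_constant_at_target(self, geometry):
        dyn = DynamicsParams(tau=5.0, sigma=1e-9, k_act_to_inact=1e-12,
                             k_inact_to_act=1e-12, dt=0.1, seed=0)
        traj, _ = simulate(geometry, dyn, 5, helix_length=8)
        pair = DistancePair.from_helices("TMD6", "TMD3")
        series = pair_distance_series(traj, pair)
        target = geometry.pair_target("active", "TMD6", "TMD3")
        np.testing.assert_allclose(series, target, atol=1e-6)

    def test_rigid_transform_invariance(self, bundle):
        rng = np.random.default_rng(2)
        coords = bundle.coords[None] + rng.normal(size=(10, bundle.n_atoms, 3))
        traj = Trajectory(bundle, coords, 0.1 * np.arange(10))
        pair = DistancePair.from_helices("TMD2", "TMD7")
        base = pair_distance_series(traj, pair)
        moved = np.empty_like(coords)
        for f in range(10):
            rot = special_ortho_group.rvs(3, random_state=rng)
            moved[f] = coords[f] @ rot.T + rng.uniform(-50, 50, 3)
        series = pair_distance_series(
            Trajectory(bundle, moved, traj.times), pair
        )
        assert np.max(np.abs(series - base)) < 1e-9

    def test_unresolvable_anchor_errors(self, bundle):
        pair = DistancePair("bad", (9999, "CA"), (366, "CA"))
        with pytest.raises(KeyError, match="bad"):
            pair_distance_series(static_trajectory(bundle, 2), pair)

    def test_helix_anchor_at_cytoplasmic_third(self, bundle):
        res, atom = helix_anchor(bundle, "TMD1")
        lo, hi = bundle.helix_annotation["TMD1"]
        assert res == lo + (hi - lo) // 3
        assert atom == "CA"


class TestProject2d:
    def test_marginal_equals_1d_histogram(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(10, 2, 5000), rng.normal(20, 3, 5000)
        density, ea, eb = project2d(a, b, bins=30)
        marginal = density.sum(axis=1) * np.diff(eb)[0]
        expected, _ = np.histogram(a, bins=ea, density=True)
        assert np.max(np.abs(marginal - expected)) < 1e-9

    def test_uniform_joint_is_flat(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, 1, 100_000), rng.uniform(0, 1, 100_000)
        density, _, _ = project2d(a, b, bins=10)
        assert density.max() / density.min() < 2.0

    def test_correlated_series_mass_on_diagonal(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 10, 20_000)
        density, ea, eb = project2d(a, a, bins=20)
        off_diagonal = density.copy()
        np.fill_diagonal(off_diagonal, 0.0)
        assert off_diagonal.max() == 0.0
        assert np.all(np.diag(density) > 0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="lengths"):
            project2d(np.arange(5.0), np.arange(6.0))


class TestOverlapCoefficient:
    def test_identical_samples_give_one(self):
        x = np.random.default_rng(6).normal(size=5000)
        assert overlap_coefficient(x, x) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert overlap_coefficient(
            np.random.default_rng(7).uniform(0, 1, 1000),
            np.random.default_rng(8).uniform(10, 11, 1000),
        ) == pytest.approx(0.0)

    def test_gaussian_closed_form(self):
        # OVL(N(0,1), N(1,1)) = 2 Phi(-1/2) ~ 0.6171
        rng = np.random.default_rng(9)
        ovl = overlap_coefficient(rng.normal(0, 1, 200_000),
                                  rng.normal(1, 1, 200_000))
        assert abs(ovl - 2 * norm.cdf(-0.5)) < 0.02

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 3000), rng.normal(2, 2, 3000)
        edges = common_grid(a, b)
        pa, _ = np.histogram(a, bins=edges, density=True)
        pb, _ = np.histogram(b, bins=edges, density=True)
        o1 = overlap_coefficient(pa, pb, edges=edges)
        o2 = overlap_coefficient(pb, pa, edges=edges)
        assert o1 == pytest.approx(o2)
        assert 0.0 <= o1 <= 1.0

    def test_incompatible_grid_errors(self):
        edges = np.linspace(0, 1, 11)
        with pytest.raises(ValueError, match="incompatible"):
            overlap_coefficient(np.ones(10), np.ones(12), edges=edges)


class TestShiftVsReference:
    def test_shift_of_constructed_mode(self):
        # distance distribution centred at 14 Å against a 9 Å reference
        rng = np.random.default_rng(11)
        series = rng.normal(14.0, 0.5, 20_000)
        shift = shift_vs_reference(series, {"TMD2-TMD7": 9.0}, "TMD2-TMD7")
        assert abs(shift - 5.0) < 0.3

    def test_series_at_reference_has_near_zero_shift(self):
        rng = np.random.default_rng(12)
        series = rng.normal(22.4, 0.4, 20_000)
        assert abs(shift_vs_reference(series, 22.4)) < 0.2

    def test_antisymmetric_under_target_swap(self):
        # 34 -> 29 Å construction and its reverse give opposite shifts
        rng = np.random.default_rng(13)
        down = rng.normal(29.0, 0.5, 20_000)
        up = rng.normal(34.0, 0.5, 20_000)
        s_down = shift_vs_reference(down, 34.0)
        s_up = shift_vs_reference(up, 29.0)
        assert abs(s_down + 5.0) < 0.3
        assert abs(s_up - 5.0) < 0.3
        assert abs(s_down + s_up) < 0.4

    def test_missing_pair_errors(self):
        with pytest.raises(KeyError, match="TMD6-TMD4"):
            shift_vs_reference(np.random.default_rng(14).normal(10, 1, 1000),
                               {"TMD6-TMD3": 22.4}, "TMD6-TMD4")


def test_per_state_mean_recovers_target_within_blocking_se(geometry):
    """Generator + analysis closed loop: state-conditional distance means."""
    dyn = DynamicsParams(tau=2.0, sigma=0.3, k_act_to_inact=1e-9,
                         k_inact_to_act=1e-9, dt=0.1, seed=15)
    traj, truth = simulate(geometry, dyn, 20_000, helix_length=8)
    pair = DistancePair.from_helices("TMD6", "TMD3")
    series = pair_distance_series(traj, pair)
    from fshrdyn.blocking import blocking_curve, plateau
    _, se, converged = plateau(blocking_curve(series))
    assert converged
    target = geometry.pair_target("active", "TMD6", "TMD3")
    assert abs(series.mean() - target) < 4 * se
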