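"""Synthetic 7TM-bundle trajectories with known two-state dynamics.

The generator emulates, at desk scale, the conformational sampling of a
class-A GPCR transmembrane bundle: seven ideal Cα helices whose axis
positions in the membrane plane fluctuate around state-dependent target
geometries (active vs inactive), with stochastic switching between the
two states.  The hidden state follows a two-state continuous-time
Markov chain discretised at the frame spacing; each helix axis follows
an Ornstein-Uhlenbeck (OU) process whose mean switches with the hidden
state ("mean-switching OU"), so transitions relax over a finite time
rather than teleporting between geometries.  Every run returns the
hidden-state labels as ground truth, enabling parameter-recovery tests
that all-atom MD cannot provide.

The protein is represented by Cα atoms only: the analysis operators
take atom selections, so atom-level detail is a fixture choice, not an
operator limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import squareform, pdist

from fshrdyn.trajio import HELIX_NAMES, Structure, Trajectory

# ideal Calpha-helix parameters
HELIX_RISE = 1.5        # Å per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # Å

#: minimal inter-axis spacing enforced on target geometries (helix packing floor)
PACKING_FLOOR = 6.0

#: default first residue number of each helix, loosely following FSHR
#: transmembrane numbering so pocket residues like T449 (TMD3) or H615
#: (TMD7) have analogues in the synthetic bundle
RESIDUE_STARTS: dict[str, int] = {
    "TMD1": 366, "TMD2": 399, "TMD3": 443, "TMD4": 487,
    "TMD5": 524, "TMD6": 571, "TMD7": 601,
}

STATES = ("inactive", "active")


class EmbeddingError(ValueError):
    """Target distance matrix not embeddable in the membrane plane."""


def _check_matrix(m: np.ndarray, label: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (7, 7):
        raise ValueError(f"{label} matrix must be 7x7, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ValueError(f"{label} matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError(f"{label} matrix must have zero diagonal")
    off = m[~np.eye(7, dtype=bool)]
    if np.any(off < PACKING_FLOOR):
        raise ValueError(
            f"{label} matrix has inter-axis distance below the "
            f"{PACKING_FLOOR} Å packing floor"
        )
    return m


@dataclass
class StateGeometry:
    """Per-state target inter-axis distance matrices for the 7TM bundle.

    ``active`` and ``inactive`` are symmetric 7x7 matrices (Å, zero
    diagonal, helix order TMD1..TMD7).  They must differ in at least one
    of the declared ``microswitch_pairs``.
    """

    active: np.ndarray
    inactive: np.ndarray
    microswitch_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("TMD6", "TMD3"), ("TMD6", "TMD5"), ("TMD2", "TMD7")]
    )
    _layouts: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.active = _check_matrix(self.active, "active")
        self.inactive = _check_matrix(self.inactive, "inactive")
        idx = {name: i for i, name in enumerate(HELIX_NAMES)}
        if not any(
            abs(self.active[idx[a], idx[b]] - self.inactive[idx[a], idx[b]]) > 1e-9
            for a, b in self.microswitch_pairs
        ):
            raise ValueError("active and inactive matrices agree on every microswitch pair")

    def matrix(self, state: str) -> np.ndarray:
        if state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {state!r}")
        return self.active if state == "active" else self.inactive

    def pair_target(self, state: str, helix_a: str, helix_b: str) -> float:
        idx = {name: i for i, name in enumerate(HELIX_NAMES)}
        return float(self.matrix(state)[idx[helix_a], idx[helix_b]])

    @classmethod
    def from_layouts(
        cls,
        active_xy: np.ndarray,
        inactive_xy: np.ndarray,
        microswitch_pairs: list[tuple[str, str]] | None = None,
    ) -> "StateGeometry":
        """Build from explicit 2-D axis layouts (7, 2); exactly embeddable."""
        active_xy = np.asarray(active_xy, float)
        inactive_xy = np.asarray(inactive_xy, float)
        kwargs = {}
        if microswitch_pairs is not None:
            kwargs["microswitch_pairs"] = microswitch_pairs
        geo = cls(
            active=squareform(pdist(active_xy)),
            inactive=squareform(pdist(inactive_xy)),
            **kwargs,
        )
        geo._layouts = {"active": active_xy, "inactive": inactive_xy}
        return geo


def default_geometry() -> StateGeometry:
    """Canonical two-state bundle: a regular heptagon of helix axes.

    The active state places the seven axes on a circle of radius 11.5 Å
    (adjacent spacing ≈ 10 Å, typical of a TM bundle).  The inactive
    state moves TMD6 4 Å toward the bundle core — the inward TMD6 motion
    that distinguishes inactive from active class-A GPCR conformations —
    shortening TMD6-TMD3, TMD6-TMD5 and TMD6-TMD7 while leaving the
    other helices in place.
    """
    angles = 2 * np.pi * np.arange(7) / 7
    active = 11.5 * np.column_stack([np.cos(angles), np.sin(angles)])
    inactive = active.copy()
    inactive[5] *= (11.5 - 4.0) / 11.5  # TMD6 (index 5) inward
    return StateGeometry.from_layouts(active, inactive)


def embed_geometry(geometry: StateGeometry, tol: float = 0.05) -> dict[str, np.ndarray]:
    """2-D axis layouts realising both target matrices, mutually aligned.

    Classical multidimensional scaling in the membrane plane, followed
    by orthogonal-Procrustes alignment of the inactive layout onto the
    active one (so state switching displaces only the helices whose
    targets differ).  Raises :class:`EmbeddingError` with the residual
    stress when the relative Frobenius misfit exceeds ``tol``.
    """
    if geometry._layouts is not None:
        return {k: v.copy() for k, v in geometry._layouts.items()}
    layouts = {}
    for state in STATES:
        d = geometry.matrix(state)
        d2 = d**2
        j = np.eye(7) - np.ones((7, 7)) / 7
        b = -0.5 * j @ d2 @ j
        w, v = np.linalg.eigh(b)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        xy = v[:, :2] * np.sqrt(np.clip(w[:2], 0.0, None))
        realized = squareform(pdist(xy))
        stress = np.linalg.norm(realized - d) / np.linalg.norm(d)
        if stress > tol:
            raise EmbeddingError(
                f"{state} target matrix is not embeddable in 2-D: "
                f"relative Frobenius stress {stress:.3f} > {tol}"
            )
        layouts[state] = xy
    r, _ = orthogonal_procrustes(
        layouts["inactive"] - layouts["inactive"].mean(0),
        layouts["active"] - layouts["active"].mean(0),
    )
    layouts["inactive"] = (
        (layouts["inactive"] - layouts["inactive"].mean(0)) @ r
        + layouts["active"].mean(0)
    )
    return layouts


# ---------------------------------------------------------------------------
# Bundle construction
# ---------------------------------------------------------------------------

def _helix_local_coords(length: int) -> np.ndarray:
    """(length, 3) ideal Cα helix around a vertical axis through the origin."""
    k = np.arange(length)
    theta = np.deg2rad(HELIX_TWIST) * k
    return np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * k,
    ])


def build_bundle(
    geometry: StateGeometry,
    helix_length: int = 25,
    state: str = "active",
    residue_starts: dict[str, int] | None = None,
    chain: str = "R",
) -> Structure:
    """Construct a Cα-only 7-helix bundle realising one state's geometry.

    Each helix is an ideal Cα helix (1.5 Å rise, 100° twist, 2.3 Å
    radius) with a vertical axis placed at the state's embedded 2-D
    position, so realized inter-axis distances match the target matrix.
    """
    if helix_length < 8:
        raise ValueError("helix_length must be at least 8 residues")
    starts = dict(residue_starts or RESIDUE_STARTS)
    layouts = embed_geometry(geometry)
    axes = layouts[state]
    local = _helix_local_coords(helix_length)
    coords, names, resnums = [], [], []
    annotation = {}
    for h, helix in enumerate(HELIX_NAMES):
        xyz = local.copy()
        xyz[:, :2] += axes[h]
        coords.append(xyz)
        names.extend(["CA"] * helix_length)
        start = starts[helix]
        resnums.extend(range(start, start + helix_length))
        annotation[helix] = (start, start + helix_length - 1)
    n = 7 * helix_length
    return Structure(
        atom_names=np.array(names),
        elements=np.full(n, "C"),
        res_names=np.full(n, "ALA"),
        res_numbers=np.array(resnums),
        chain_ids=np.full(n, chain),
        coords=np.vstack(coords),
        helix_annotation=annotation,
        ligand_selector=None,
    )


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

@dataclass
class DynamicsParams:
    """Parameters of the mean-switching OU helix dynamics.

    tau: OU relaxation time (ns); sigma: stationary SD of each axis
    coordinate (Å); k_act_to_inact / k_inact_to_act: switching rates
    (ns⁻¹) of the hidden two-state chain; dt: frame spacing (ns).
    Stability requires dt < tau / 5.
    """

    tau: float = 5.0
    sigma: float = 1.0
    k_act_to_inact: float = 0.005
    k_inact_to_act: float = 0.005
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau", "sigma", "k_act_to_inact", "k_inact_to_act", "dt"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.dt >= self.tau / 5:
            raise ValueError(f"dt ({self.dt}) must be below tau/5 ({self.tau / 5})")

    @property
    def stationary_active_fraction(self) -> float:
        """Equilibrium active occupancy k_ia / (k_ai + k_ia)."""
        return self.k_inact_to_act / (self.k_act_to_inact + self.k_inact_to_act)


@dataclass
class GroundTruth:
    """Hidden-state record of a synthetic run."""

    states: np.ndarray            # per-frame labels, "active" | "inactive"
    transition_count: int
    occupancy: dict[str, float]   # state -> fraction of frames

    def __post_init__(self) -> None:
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancies sum to {total}, expected 1")
        changes = int(np.sum(self.states[1:] != self.states[:-1]))
        if changes != self.transition_count:
            raise ValueError("transition_count inconsistent with state labels")


def simulate(
    geometry: StateGeometry,
    dynamics: DynamicsParams,
    n_frames: int,
    helix_length: int = 25,
    start_state: str | None = None,
    residue_starts: dict[str, int] | None = None,
    structure: Structure | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate a two-state switching 7TM trajectory with ground truth.

    The hidden state is a two-state Markov chain discretised at ``dt``
    (per-step switch probability ``1 - exp(-k dt)``); each helix axis
    position is an OU process relaxing toward the current state's
    embedded layout with time constant ``tau`` and stationary SD
    ``sigma`` per coordinate.  If ``structure`` (e.g. the output of
    :func:`place_ligand`) is given, its ligand atoms are carried rigidly
    through all frames; otherwise an apo bundle is built internally.

    Returns the trajectory and the per-frame hidden-state ground truth.
    Identical seeds give bit-identical output.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    if start_state is None:
        start_state = "active"
    if start_state not in STATES:
        raise ValueError(f"start_state must be one of {STATES}")

    if structure is None:
        structure = build_bundle(
            geometry, helix_length=helix_length, state=start_state,
            residue_starts=residue_starts,
        )
    ligand_mask = structure.ligand_mask()
    protein_idx = np.flatnonzero(~ligand_mask)
    if len(protein_idx) != 7 * helix_length:
        # infer helix length from the structure instead of the argument
        helix_length = len(protein_idx) // 7
        if 7 * helix_length != len(protein_idx):
            raise ValueError("protein atom count is not divisible into 7 helices")

    layouts = embed_geometry(geometry)
    means = np.stack([layouts["inactive"], layouts["active"]])  # (2, 7, 2)

    rng = np.random.default_rng(dynamics.seed)
    dt, tau, sigma = dynamics.dt, dynamics.tau, dynamics.sigma
    decay = math.exp(-dt / tau)
    kick = sigma * math.sqrt(1.0 - decay**2)
    p_switch = np.array([
        1.0 - math.exp(-dynamics.k_inact_to_act * dt),   # inactive -> active
        1.0 - math.exp(-dynamics.k_act_to_inact * dt),   # active -> inactive
    ])

    # hidden chain
    states = np.empty(n_frames, dtype=np.int8)
    states[0] = 1 if start_state == "active" else 0
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        s = states[t - 1]
        states[t] = 1 - s if u[t - 1] < p_switch[s] else s

    # OU axis positions (n_frames, 7, 2)
    axes = np.empty((n_frames, 7, 2))
    axes[0] = means[states[0]] + sigma * rng.standard_normal((7, 2))
    noise = rng.standard_normal((n_frames - 1, 7, 2))
    for t in range(1, n_frames):
        mu = means[states[t]]
        axes[t] = mu + (axes[t - 1] - mu) * decay + kick * noise[t - 1]

    # assemble frames: helices rebuilt from axes, ligand rigid
    local = _helix_local_coords(helix_length)
    coords = np.empty((n_frames, structure.n_atoms, 3))
    coords[:] = structure.coords  # ligand (and z, local xy) template
    prot = protein_idx.reshape(7, helix_length)
    for h in range(7):
        idx = prot[h]
        coords[:, idx, 0] = local[:, 0] + axes[:, h, 0][:, None]
        coords[:, idx, 1] = local[:, 1] + axes[:, h, 1][:, None]
        coords[:, idx, 2] = local[:, 2]

    times = dt * np.arange(n_frames)
    traj = Trajectory(structure=structure, coords=coords, times=times)
    labels = np.where(states == 1, "active", "inactive")
    occ_active = float(np.mean(states == 1))
    truth = GroundTruth(
        states=labels,
        transition_count=int(np.sum(states[1:] != states[:-1])),
        occupancy={"active": occ_active, "inactive": 1.0 - occ_active},
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Ligand placement
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def place_ligand(
    structure: Structure,
    pocket_residues: list[int] | None,
    n_atoms: int | None = None,
    contact_distance: float = 3.4,
    seed: int = 0,
    max_retries: int = 200,
) -> Structure:
    """Append ligand pseudo-atoms contacting exactly the pocket residues.

    One ligand atom is placed within ``contact_distance`` of each
    declared pocket residue, along the direction (searched over a
    deterministic unit-vector grid) that maximises clearance from all
    non-pocket atoms; any surplus atoms go near the pocket centroid when
    clearance allows.  The construction guarantees, at frame 0, a
    minimum ligand distance below ``contact_distance`` for every pocket
    residue and above ``contact_distance + 1`` Å for every other residue
    — a geometry that pins down the expected contact set exactly.  An
    empty/None pocket returns the structure unchanged (apo pass-through).
    """
    if not pocket_residues:
        return structure
    res_map = structure.residues
    missing = [r for r in pocket_residues if r not in res_map]
    if missing:
        raise KeyError(f"pocket residues not in structure: {missing}")
    if n_atoms is None:
        n_atoms = len(pocket_residues)
    if n_atoms < len(pocket_residues):
        raise ValueError("need at least one ligand atom per pocket residue")

    rng = np.random.default_rng(seed)
    clearance = contact_distance + 1.0
    pocket_set = set(pocket_residues)
    pocket_xyz = np.vstack([structure.coords[res_map[r]] for r in pocket_residues])
    centroid = pocket_xyz.mean(axis=0)
    other_xyz = np.vstack([
        structure.coords[res_map[r]] for r in res_map if r not in pocket_set
    ]) if len(res_map) > len(pocket_set) else np.empty((0, 3))

    directions = _fibonacci_sphere(400)
    reach = 0.92 * contact_distance
    atoms: list[np.ndarray] = []
    for r in pocket_residues:
        anchor_atoms = structure.coords[res_map[r]]
        # anchor: the residue atom closest to the pocket centroid
        a = anchor_atoms[np.argmin(np.linalg.norm(anchor_atoms - centroid, axis=1))]
        candidates = a + reach * directions      # (400, 3)
        if len(other_xyz):
            dmin = np.min(
                np.linalg.norm(candidates[:, None] - other_xyz[None], axis=2), axis=1
            )
        else:
            dmin = np.full(len(candidates), np.inf)
        best = int(np.argmax(dmin))
        if dmin[best] <= clearance:
            raise RuntimeError(
                f"could not place a ligand atom at residue {r}: best "
                f"clearance {dmin[best]:.2f} Å <= required {clearance:.2f} Å "
                f"(pocket too tight for contact_distance="
                f"{contact_distance} Å)"
            )
        atoms.append(candidates[best])
    for _ in range(n_atoms - len(pocket_residues)):
        for _attempt in range(max_retries):
            pos = centroid + rng.normal(scale=0.5, size=3)
            if (
                len(other_xyz) == 0
                or np.min(np.linalg.norm(other_xyz - pos, axis=1)) > clearance
            ):
                atoms.append(pos)
                break
        else:
            raise RuntimeError(
                f"could not place surplus ligand atom near the pocket "
                f"centroid after {max_retries} attempts"
            )
    placement = np.asarray(atoms)
    # construction check: every pocket residue must actually be in contact
    for r in pocket_residues:
        dmin = np.min(np.linalg.norm(
            structure.coords[res_map[r]][:, None] - placement[None], axis=2
        ))
        if dmin >= contact_distance:
            raise RuntimeError(
                f"pocket residue {r} ended up {dmin:.2f} Å from the ligand, "
                f"outside contact_distance={contact_distance} Å"
            )

    n_lig = len(placement)
    return Structure(
        atom_names=np.concatenate([structure.atom_names,
                                   [f"C{i + 1}" for i in range(n_lig)]]),
        elements=np.concatenate([structure.elements, ["C"] * n_lig]),
        res_names=np.concatenate([structure.res_names, ["LIG"] * n_lig]),
        res_numbers=np.concatenate([structure.res_numbers, [900] * n_lig]),
        chain_ids=np.concatenate([structure.chain_ids, ["L"] * n_lig]),
        coords=np.vstack([structure.coords, placement]),
        helix_annotation=dict(structure.helix_annotation),
        ligand_selector="LIG",
    )
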