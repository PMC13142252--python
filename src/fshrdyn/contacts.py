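"""Ligand-residue contacts, trailing-window occupancy maps, comparisons.

A residue is "in contact" with the ligand in a frame when the minimum
distance over all (ligand atom, residue atom) pairs is at or below the
cutoff (default 3.5 Å, the standard heavy-atom contact convention, read
inclusively).  Contact occupancy is the fraction of frames in a
trailing analysis window (default the last 40 ns of the trajectory) in
which the residue is in contact; persistent contacts are those whose
occupancy reaches a minimum fraction (default 0.25).  Maps from several
replicates/systems are compared as presence/absence tables so that,
e.g., a contact seen in only one replicate of one variant stands out.

Distance queries use a KD-tree on the ligand atoms; an O(n²) scan gives
the same result and serves as the test oracle.

No periodic-boundary minimum-image handling is applied: inputs are
assumed whole and non-periodic (imaged trajectories).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from fshrdyn.trajio import BACKBONE_ATOMS, Structure, Trajectory

logger = logging.getLogger(__name__)

ATOM_SCOPES = ("sidechain", "heavy", "ca")


@dataclass(frozen=True)
class ContactConfig:
    """Parameters of contact-map analysis.

    cutoff: contact distance in Å (inclusive).  window: trailing window
    length in ns, measured back from the final frame.  atom_scope:
    which protein atoms count ("sidechain" heavy atoms, all "heavy"
    atoms, or "ca").  min_persistence: occupancy fraction above which a
    contact is called stable.
    """

    cutoff: float = 3.5
    window: float = 40.0
    atom_scope: str = "sidechain"
    min_persistence: float = 0.25

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.window <= 0:
            raise ValueError(f"window must be positive, got {self.window}")
        if self.atom_scope not in ATOM_SCOPES:
            raise ValueError(f"atom_scope must be one of {ATOM_SCOPES}")
        if not 0 <= self.min_persistence <= 1:
            raise ValueError("min_persistence must lie in [0, 1]")


@dataclass
class ContactMap:
    """Ligand-contact occupancy per residue over a trailing window."""

    system: str
    replicate: str
    occupancy: dict[int, float]     # residue number -> fraction in [0, 1]
    n_frames: int
    res_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("a contact map needs at least one frame")
        bad = {r: f for r, f in self.occupancy.items() if not 0 <= f <= 1}
        if bad:
            raise ValueError(f"occupancy fractions outside [0, 1]: {bad}")

    def persistent(self, min_fraction: float = 0.25) -> list[int]:
        """Residues whose occupancy reaches ``min_fraction``, sorted."""
        return sorted(r for r, f in self.occupancy.items() if f >= min_fraction)


def _scope_mask(structure: Structure, atom_scope: str) -> np.ndarray:
    """Protein atoms participating in contact queries for a given scope."""
    protein = structure.protein_mask()
    heavy = structure.elements != "H"
    if atom_scope == "heavy":
        return protein & heavy
    if atom_scope == "ca":
        return protein & (structure.atom_names == "CA")
    # sidechain: heavy atoms off the backbone; Cα-only fixtures have
    # none, so fall back to Cα with a warning rather than failing
    mask = protein & heavy & ~np.isin(structure.atom_names, list(BACKBONE_ATOMS))
    if not mask.any():
        logger.warning(
            "no side-chain heavy atoms found (Cα-only structure?); "
            "falling back to Cα scope"
        )
        return protein & (structure.atom_names == "CA")
    return mask


def frame_contacts(
    frame: np.ndarray,
    ligand_indices: np.ndarray,
    protein_indices: np.ndarray,
    res_numbers: np.ndarray,
    cutoff: float = 3.5,
) -> set[int]:
    """Residues with any scoped atom within ``cutoff`` of any ligand atom.

    ``frame`` is the (n_atoms, 3) coordinate array; ``res_numbers`` maps
    every atom to its residue.  The cutoff is inclusive.  An empty
    ligand selection is an error (an apo system has no contacts to ask
    about).
    """
    ligand_indices = np.asarray(ligand_indices)
    protein_indices = np.asarray(protein_indices)
    if ligand_indices.size == 0:
        raise ValueError("empty ligand atom set: contacts undefined for apo system")
    if protein_indices.size == 0:
        raise ValueError("empty protein atom set")
    tree = cKDTree(frame[ligand_indices])
    dmin, _ = tree.query(frame[protein_indices], k=1)
    hit = dmin <= cutoff
    return set(int(r) for r in np.unique(res_numbers[protein_indices[hit]]))


def frame_contacts_bruteforce(
    frame: np.ndarray,
    ligand_indices: np.ndarray,
    protein_indices: np.ndarray,
    res_numbers: np.ndarray,
    cutoff: float = 3.5,
) -> set[int]:
    """All-pairs reference implementation of :func:`frame_contacts`."""
    ligand_indices = np.asarray(ligand_indices)
    protein_indices = np.asarray(protein_indices)
    if ligand_indices.size == 0:
        raise ValueError("empty ligand atom set: contacts undefined for apo system")
    out: set[int] = set()
    for i in protein_indices:
        for j in ligand_indices:
            if np.linalg.norm(frame[i] - frame[j]) <= cutoff:
                out.add(int(res_numbers[i]))
                break
    return out


def occupancy_map(
    traj: Trajectory,
    config: ContactConfig = ContactConfig(),
    system: str = "",
    replicate: str = "",
) -> ContactMap:
    """Contact occupancy per residue over the trailing analysis window.

    Frames with time >= t_end - window enter the window (the boundary
    frame is included).  The trajectory must span at least the window;
    otherwise the error suggests overriding ``window``.
    """
    structure = traj.structure
    ligand_idx = np.flatnonzero(structure.ligand_mask())
    if ligand_idx.size == 0:
        raise ValueError(
            "structure has no ligand atoms (apo system queried for contacts)"
        )
    span = float(traj.times[-1] - traj.times[0])
    if span < config.window:
        raise ValueError(
            f"trajectory spans {span:.3f} ns, shorter than the "
            f"{config.window} ns window; pass a ContactConfig with a "
            f"smaller window to analyse it"
        )
    in_window = traj.times >= traj.times[-1] - config.window
    protein_idx = np.flatnonzero(_scope_mask(structure, config.atom_scope))
    counts: dict[int, int] = {}
    n_frames = int(in_window.sum())
    for f in np.flatnonzero(in_window):
        for res in frame_contacts(
            traj.coords[f], ligand_idx, protein_idx,
            structure.res_numbers, config.cutoff,
        ):
            counts[res] = counts.get(res, 0) + 1
    res_names = {
        int(r): str(structure.res_names[structure.residues[r][0]])
        for r in counts
    }
    return ContactMap(
        system=system,
        replicate=replicate,
        occupancy={r: c / n_frames for r, c in sorted(counts.items())},
        n_frames=n_frames,
        res_names=res_names,
    )


def compare_maps(maps: list[ContactMap], min_fraction: float = 0.25) -> pd.DataFrame:
    """Presence/absence table of persistent contacts across maps.

    Rows are residue numbers (union over maps); columns are
    (system, replicate) pairs; entries are booleans (occupancy >=
    ``min_fraction``).  The ``attrs['diff']`` list names residues whose
    presence differs between any two maps — e.g. a contact detected in
    only one replicate of one variant.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 contact maps to compare")
    residues = sorted(set().union(*(m.occupancy.keys() for m in maps)))
    columns = pd.MultiIndex.from_tuples(
        [(m.system, m.replicate) for m in maps], names=["system", "replicate"]
    )
    data = np.array(
        [[m.occupancy.get(r, 0.0) >= min_fraction for m in maps] for r in residues],
        dtype=bool,
    ).reshape(len(residues), len(maps))
    table = pd.DataFrame(data, index=pd.Index(residues, name="residue"), columns=columns)
    table.attrs["diff"] = [
        int(r) for r in residues
        if table.loc[r].nunique() > 1
    ]
    return table
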