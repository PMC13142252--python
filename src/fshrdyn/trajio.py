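"""Structures, trajectories, atom selections and replicate labelling.

Units and conventions used throughout the package: coordinates in
angstrom (Å), times in nanoseconds (ns), residue numbers 1-based and
matching receptor sequence numbering (so a mutation label like D408
maps directly onto residue 408), helix ranges inclusive on both ends.

The native trajectory format is the multi-model PDB (one MODEL per
frame), which is plain text and round-trips coordinates at the format's
3-decimal precision.  Binary formats (DCD/XTC) enter through the
frame-iterator adapter contract of :func:`trajectory_from_frames`
rather than a built-in reader.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

HELIX_NAMES = tuple(f"TMD{i}" for i in range(1, 8))

#: backbone atom names excluded from the "sidechain" scope
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class Structure:
    """Topology-free structure: ordered atoms plus helix/ligand annotation.

    Attributes
    ----------
    atom_names, elements, res_names : arrays of str, one per atom
    res_numbers : int array, 1-based author numbering
    chain_ids : str array
    coords : (n_atoms, 3) float array, Å — the reference frame
    helix_annotation : mapping ``TMD1``..``TMD7`` -> inclusive
        (first, last) residue-number range
    ligand_selector : residue name (e.g. ``"LIG"``) or ``"chain:X"``
        marking ligand atoms; ``None`` for apo structures
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_numbers: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    helix_annotation: dict[str, tuple[int, int]] = field(default_factory=dict)
    ligand_selector: str | None = None

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype="U4")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.res_names = np.asarray(self.res_names, dtype="U4")
        self.res_numbers = np.asarray(self.res_numbers, dtype=np.int64)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = self.n_atoms
        for arr, label in [
            (self.elements, "elements"), (self.res_names, "res_names"),
            (self.res_numbers, "res_numbers"), (self.chain_ids, "chain_ids"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._validate_helix_annotation()

    def _validate_helix_annotation(self) -> None:
        ranges = sorted(self.helix_annotation.items(), key=lambda kv: kv[1][0])
        prev_hi = None
        for name, (lo, hi) in ranges:
            if lo > hi:
                raise ValueError(f"helix {name} has empty range ({lo}, {hi})")
            if prev_hi is not None and lo <= prev_hi:
                raise ValueError(f"helix ranges overlap at {name}")
            prev_hi = hi

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residues(self) -> dict[int, np.ndarray]:
        """Residue number -> array of atom indices (file order)."""
        out: dict[int, list[int]] = {}
        for i, rn in enumerate(self.res_numbers):
            out.setdefault(int(rn), []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def ligand_mask(self) -> np.ndarray:
        """Boolean mask of ligand atoms (all-False when apo)."""
        if self.ligand_selector is None:
            return np.zeros(self.n_atoms, dtype=bool)
        if self.ligand_selector.startswith("chain:"):
            return self.chain_ids == self.ligand_selector.split(":", 1)[1]
        return self.res_names == self.ligand_selector

    def protein_mask(self) -> np.ndarray:
        return ~self.ligand_mask()

    def helix_mask(self, name: str) -> np.ndarray:
        if name not in self.helix_annotation:
            raise KeyError(
                f"unknown helix {name!r}; valid names: "
                f"{sorted(self.helix_annotation)}"
            )
        lo, hi = self.helix_annotation[name]
        return (self.res_numbers >= lo) & (self.res_numbers <= hi) & self.protein_mask()

    def atom_index(self, res_number: int, atom_name: str) -> int:
        """Index of the unique atom (res_number, atom_name); KeyError if absent."""
        hits = np.flatnonzero(
            (self.res_numbers == res_number) & (self.atom_names == atom_name)
        )
        if len(hits) == 0:
            raise KeyError(f"no atom {atom_name!r} in residue {res_number}")
        return int(hits[0])


@dataclass
class Trajectory:
    """Ordered frames of coordinates bound to a :class:`Structure`.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``times`` in ns,
    strictly increasing.
    """

    structure: Structure
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords shape {self.coords.shape} is not (frames, atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise ValueError(
                f"trajectory has {self.coords.shape[1]} atoms per frame, "
                f"structure has {self.structure.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length != frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dt(self) -> float:
        """Frame spacing in ns (0 for single-frame trajectories)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


@dataclass
class ReplicateSet:
    """Independent replicates (R1..Rn) of one system / ligand state."""

    system: str
    ligand_state: str  # "apo" | "holo"
    replicates: list[Trajectory]

    def __post_init__(self) -> None:
        if self.ligand_state not in ("apo", "holo"):
            raise ValueError(f"ligand_state must be 'apo' or 'holo', got {self.ligand_state!r}")
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate required")
        ref = self.replicates[0].structure
        for r in self.replicates[1:]:
            if r.structure is not ref and r.structure.n_atoms != ref.n_atoms:
                raise ValueError("replicates must share one structure")

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.replicates)

    def labels(self) -> list[str]:
        return [f"R{i + 1}" for i in range(len(self.replicates))]


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed, with line-level validation for clear errors)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, record_element: str) -> str:
    if record_element.strip():
        return record_element.strip().upper()
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped and stripped[0].isalpha():
        return stripped[0].upper()
    logger.warning("cannot infer element for atom %r; treating as carbon", atom_name)
    return "C"


def _validate_pdb_lines(lines: Sequence[str]) -> None:
    for ln, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) >= 6:
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {ln}: truncated coordinate record: {line.rstrip()!r}")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {ln}: malformed ATOM/HETATM record: {exc}") from exc


def _structure_from_atom_array(
    arr: bst.AtomArray,
    helix_annotation: Mapping[str, tuple[int, int]] | None,
    ligand_selector: str | None,
) -> Structure:
    elements = np.array(
        [_infer_element(n, e) for n, e in zip(arr.atom_name, arr.element)], dtype="U2"
    )
    return Structure(
        atom_names=arr.atom_name,
        elements=elements,
        res_names=arr.res_name,
        res_numbers=arr.res_id,
        chain_ids=arr.chain_id,
        coords=arr.coord,
        helix_annotation=dict(helix_annotation or {}),
        ligand_selector=ligand_selector,
    )


def read_structure(
    path,
    helix_annotation: Mapping[str, tuple[int, int]] | None = None,
    ligand_selector: str | None = None,
) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    HETATM records are kept; they become ligand atoms when they match
    ``ligand_selector``.  Missing element columns are inferred from the
    first letter of the atom name (falling back to carbon with a warning).
    """
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    _validate_pdb_lines(lines)
    pdb = PDBFile.read(io.StringIO(text))
    if pdb.get_model_count() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records (empty structure)")
    arr = pdb.get_structure(model=1)
    return _structure_from_atom_array(arr, helix_annotation, ligand_selector)


def _to_atom_array(structure: Structure, coords: np.ndarray) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = structure.atom_names
    arr.element = structure.elements
    arr.res_name = structure.res_names
    arr.res_id = structure.res_numbers
    arr.chain_id = structure.chain_ids
    arr.hetero = structure.ligand_mask()
    return arr


def write_structure(path, structure: Structure) -> None:
    """Write a single-model PDB (3-decimal coordinate precision)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure, structure.coords))
    pdb.write(str(path))


def read_trajectory(
    path,
    structure: Structure | None = None,
    dt: float = 0.1,
    t0: float = 0.0,
    helix_annotation: Mapping[str, tuple[int, int]] | None = None,
    ligand_selector: str | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL).

    Frame times are not stored in PDB files; they are reconstructed as
    ``t0 + i * dt`` (ns).  When ``structure`` is given every model must
    match its atom count; the offending model index is reported otherwise.
    """
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    _validate_pdb_lines(lines)
    # per-model atom counts, for a precise mismatch error
    counts: list[int] = []
    current = 0
    in_model = False
    for line in lines:
        if line.startswith("MODEL"):
            in_model, current = True, 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            current += 1
    if not in_model and not counts and current > 0:
        counts = [current]  # single implicit model
    if not counts or all(c == 0 for c in counts):
        raise PDBParseError(f"{path}: no models with atoms")
    if structure is not None:
        for i, c in enumerate(counts, start=1):
            if c != structure.n_atoms:
                raise PDBParseError(
                    f"{path}: model {i} has {c} atoms, structure has {structure.n_atoms}"
                )
    pdb = PDBFile.read(io.StringIO(text))
    coords = pdb.get_coord(model=None)  # (n_models, n_atoms, 3)
    if structure is None:
        arr = pdb.get_structure(model=1)
        structure = _structure_from_atom_array(arr, helix_annotation, ligand_selector)
    times = t0 + dt * np.arange(coords.shape[0])
    return Trajectory(structure=structure, coords=np.asarray(coords, float), times=times)


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a multi-model PDB, one MODEL per frame."""
    n_frames, n_atoms = traj.coords.shape[:2]
    stack = bst.AtomArrayStack(n_frames, n_atoms)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    template = _to_atom_array(traj.structure, traj.structure.coords)
    for name in ("atom_name", "element", "res_name", "res_id", "chain_id", "hetero"):
        stack.set_annotation(name, template.get_annotation(name))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def trajectory_from_frames(
    structure: Structure,
    frames: Iterable[np.ndarray],
    dt: float = 0.1,
    t0: float = 0.0,
) -> Trajectory:
    """Adapter contract for external frame iterators (e.g. DCD/XTC readers).

    Any iterable yielding (n_atoms, 3) arrays — such as a generator over
    an MDAnalysis or mdtraj trajectory — can be materialised into a
    :class:`Trajectory` without this package knowing the binary format.
    """
    coords = np.stack([np.asarray(f, float) for f in frames])
    times = t0 + dt * np.arange(coords.shape[0])
    return Trajectory(structure=structure, coords=coords, times=times)


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
# Grammar (MDAnalysis-flavoured, "and" binds tighter than "or"):
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "name" NAME | "resid" N | "resid" N-M | "helix" TMDk
#               | "ligand" | "protein" | "all"


def _parse_selection(structure: Structure, spec: str) -> np.ndarray:
    tokens = spec.replace("(", " ").replace(")", " ").split()
    if not tokens:
        raise ValueError("empty selection expression")
    pos = 0

    def factor() -> np.ndarray:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"incomplete selection expression: {spec!r}")
        tok = tokens[pos].lower()
        pos += 1
        if tok == "name":
            value = tokens[pos]; pos += 1
            return structure.atom_names == value
        if tok == "resid":
            value = tokens[pos]; pos += 1
            if "-" in value.lstrip("-"):
                lo_s, hi_s = value.rsplit("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(value)
            return (structure.res_numbers >= lo) & (structure.res_numbers <= hi)
        if tok == "helix":
            value = tokens[pos]; pos += 1
            return structure.helix_mask(value)
        if tok == "ligand":
            return structure.ligand_mask()
        if tok == "protein":
            return structure.protein_mask()
        if tok == "all":
            return np.ones(structure.n_atoms, dtype=bool)
        raise ValueError(f"unknown selection token {tok!r} in {spec!r}")

    def term() -> np.ndarray:
        nonlocal pos
        mask = factor()
        while pos < len(tokens) and tokens[pos].lower() == "and":
            pos += 1
            mask = mask & factor()
        return mask

    mask = term()
    while pos < len(tokens) and tokens[pos].lower() == "or":
        pos += 1
        mask = mask | term()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens {tokens[pos:]} in selection {spec!r}")
    return mask


def select(structure: Structure, spec: str) -> np.ndarray:
    """Evaluate a selection expression to an ordered array of atom indices.

    Supported factors: ``name <atom>``, ``resid N`` / ``resid N-M``
    (inclusive), ``helix TMDk``, ``ligand``, ``protein``, ``all``;
    combinable with ``and`` / ``or`` (``and`` binds tighter).  The result
    preserves file order and may be empty.
    """
    return np.flatnonzero(_parse_selection(structure, spec))
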