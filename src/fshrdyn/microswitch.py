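"""TMD-TMD microswitch distances, projections, overlap and shifts.

Rearrangements of a handful of inter-helix ("microswitch") distances —
TMD6-TMD3, TMD6-TMD5, TMD2-TMD7 and friends — distinguish active from
inactive class-A GPCR conformations.  This module extracts per-frame
distance series for declared helix/residue anchor pairs, summarises
them as histogram+KDE distributions, projects two series into a joint
density (the free-energy-well picture), quantifies the overlap between
two distance distributions, and reports the signed shift of a
distribution's primary peak relative to a reference (e.g. cryo-EM)
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fshrdyn.activation import IndexSeries, StateDistribution, distribution
from fshrdyn.trajio import Structure, Trajectory

#: fraction of the helix range (from its start) at which the default
#: anchor residue sits; one third of the way along the helix, on the
#: cytoplasmic side where activation microswitches live
ANCHOR_FRACTION = 1 / 3


def helix_anchor(structure: Structure, helix: str, atom_name: str = "CA") -> tuple[int, str]:
    """Default anchor for a helix-only pair spec: Cα at the cytoplasmic third.

    The anchor residue sits ``ANCHOR_FRACTION`` of the way into the
    helix's residue range.  Override by declaring an explicit
    (residue, atom) anchor on the pair.
    """
    if helix not in structure.helix_annotation:
        raise KeyError(
            f"unknown helix {helix!r}; valid: {sorted(structure.helix_annotation)}"
        )
    lo, hi = structure.helix_annotation[helix]
    res = lo + int((hi - lo) * ANCHOR_FRACTION)
    return res, atom_name


@dataclass
class DistancePair:
    """Named anchor pair, each anchor a (residue, atom) or a helix name."""

    name: str
    anchor_a: tuple[int, str] | str
    anchor_b: tuple[int, str] | str

    def resolve(self, structure: Structure) -> tuple[int, int]:
        """Atom indices of both anchors; helix names use :func:`helix_anchor`."""
        out = []
        for anchor in (self.anchor_a, self.anchor_b):
            if isinstance(anchor, str):
                res, atom = helix_anchor(structure, anchor)
            else:
                res, atom = anchor
            try:
                out.append(structure.atom_index(res, atom))
            except KeyError as exc:
                raise KeyError(f"pair {self.name!r}: unresolvable anchor: {exc}") from exc
        a, b = out
        if a == b:
            raise ValueError(f"pair {self.name!r}: both anchors resolve to the same atom")
        return a, b

    @classmethod
    def from_helices(cls, helix_a: str, helix_b: str) -> "DistancePair":
        return cls(name=f"{helix_a}-{helix_b}", anchor_a=helix_a, anchor_b=helix_b)


def pair_distance_series(traj: Trajectory, pair: DistancePair) -> np.ndarray:
    """Per-frame Euclidean anchor-anchor distance (Å)."""
    a, b = pair.resolve(traj.structure)
    return np.linalg.norm(traj.coords[:, a] - traj.coords[:, b], axis=1)


def distance_distribution(
    series: np.ndarray,
    bins: int = 60,
    bandwidth: float | str | None = None,
) -> StateDistribution:
    """Histogram/KDE summary of one distance series (blocking SD attached)."""
    return distribution(np.asarray(series, float), bins=bins, bandwidth=bandwidth)


def project2d(
    series_a: np.ndarray,
    series_b: np.ndarray,
    bins: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint density of two distance series on a ``bins``x``bins`` grid.

    Returns (density, edges_a, edges_b) with the density normalized so
    that sum(density) * da * db = 1; high-density cells mark highly
    populated conformations (free-energy wells).  Marginalising over
    either axis reproduces the corresponding 1-D histogram exactly.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.shape} vs {b.shape}")
    density, ea, eb = np.histogram2d(a, b, bins=bins, density=True)
    return density, ea, eb


def common_grid(
    series_a: np.ndarray, series_b: np.ndarray, bins: int = 60
) -> np.ndarray:
    """Shared bin edges spanning the union of both series' ranges."""
    lo = min(float(np.min(series_a)), float(np.min(series_b)))
    hi = max(float(np.max(series_a)), float(np.max(series_b)))
    if hi <= lo:
        hi = lo + 1e-6
    return np.linspace(lo, hi, bins + 1)


def overlap_coefficient(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    edges: np.ndarray | None = None,
    bins: int = 60,
) -> float:
    """Overlap coefficient of two samples or binned densities, in [0, 1].

    With raw samples, both are histogrammed on a common grid (union of
    ranges, ``bins`` bins) and the overlap is sum_bins min(p_a, p_b) *
    binwidth.  With pre-binned densities, ``edges`` must be the shared
    grid; mismatched grids are an error, not silently rebinned.
    Identical distributions give 1, disjoint supports 0.
    """
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if edges is not None:
        edges = np.asarray(edges, float)
        if len(a) != len(edges) - 1 or len(b) != len(edges) - 1:
            raise ValueError(
                f"density lengths ({len(a)}, {len(b)}) incompatible with "
                f"{len(edges) - 1} bins"
            )
        pa, pb = a, b
    else:
        edges = common_grid(a, b, bins=bins)
        pa, _ = np.histogram(a, bins=edges, density=True)
        pb, _ = np.histogram(b, bins=edges, density=True)
    widths = np.diff(edges)
    return float(np.sum(np.minimum(pa, pb) * widths))


def shift_vs_reference(
    dist: StateDistribution | np.ndarray,
    reference: float | dict[str, float],
    pair_name: str | None = None,
) -> float:
    """Signed displacement (Å) of the primary KDE mode from a reference.

    ``reference`` may be a plain distance or a mapping pair-name ->
    distance (e.g. cryo-EM values); in the latter case ``pair_name``
    selects the entry and a missing pair is an error.  Positive shift =
    the sampled distance distribution peaks above the reference.
    """
    if isinstance(reference, dict):
        if pair_name is None:
            raise ValueError("pair_name required with a reference table")
        if pair_name not in reference:
            raise KeyError(
                f"pair {pair_name!r} absent from reference table "
                f"(has: {sorted(reference)})"
            )
        ref = float(reference[pair_name])
    else:
        ref = float(reference)
    if ref <= 0:
        raise ValueError(f"reference distance must be positive, got {ref}")
    if isinstance(dist, StateDistribution):
        mode = dist.primary_mode
    else:
        mode = distance_distribution(np.asarray(dist, float)).primary_mode
    return float(mode - ref)
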