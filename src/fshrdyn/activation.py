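"""Activation-index computation, state classification and distributions.

Class-A GPCR conformations can be scored by a scalar activation index —
a linear combination of a few inter-residue distances whose coefficients
were trained on annotated active/inactive structures (the A100-style
index).  Per frame,

    index_t = intercept + sum_i coeff_i * d_i(t)        [d_i in Å]

and frames are classified by two thresholds: index below the inactive
threshold (default 0) -> inactive state, above the active threshold
(default 55) -> active state, in between -> partially activated.

The published coefficient set is external training output, not a result
of this package; the model therefore enters as replaceable configuration
(:class:`ActivationModel`), and the synthetic calibration helper
:func:`calibrated_model` produces a model with known state separation
for generator-driven tests.

Because consecutive frames are autocorrelated, the standard deviation
attached to a distribution summary always comes from the blocking
module, never from the naive SD of the mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from fshrdyn.blocking import blocking_curve, plateau
from fshrdyn.trajio import Structure, Trajectory

logger = logging.getLogger(__name__)

STATE_LABELS = ("inactive", "partial", "active")


@dataclass
class ActivationModel:
    """Linear distance-based activation index.

    descriptors: ordered (res_i, atom_i, res_j, atom_j) anchor pairs;
    coefficients: one per descriptor (1/Å); intercept: dimensionless.
    """

    descriptors: list[tuple[int, str, int, str]]
    coefficients: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if len(self.coefficients) != len(self.descriptors):
            raise ValueError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.descriptors)} descriptors"
            )

    def resolve(self, structure: Structure) -> list[tuple[int, int]]:
        """Atom-index pairs for each descriptor; KeyError names the anchor."""
        pairs = []
        for res_i, atom_i, res_j, atom_j in self.descriptors:
            try:
                a = structure.atom_index(res_i, atom_i)
                b = structure.atom_index(res_j, atom_j)
            except KeyError as exc:
                raise KeyError(
                    f"activation-model anchor unresolvable: "
                    f"({res_i}:{atom_i}, {res_j}:{atom_j}): {exc}"
                ) from exc
            pairs.append((a, b))
        return pairs

    def to_config(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "descriptors": [
                {"res_i": ri, "atom_i": ai, "res_j": rj, "atom_j": aj,
                 "coeff": float(c)}
                for (ri, ai, rj, aj), c in zip(self.descriptors, self.coefficients)
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ActivationModel":
        descriptors = [
            (int(d["res_i"]), str(d["atom_i"]), int(d["res_j"]), str(d["atom_j"]))
            for d in cfg["descriptors"]
        ]
        coefficients = [float(d["coeff"]) for d in cfg["descriptors"]]
        return cls(descriptors, np.array(coefficients), float(cfg.get("intercept", 0.0)))


@dataclass(frozen=True)
class StateThresholds:
    """Classification thresholds on the activation index."""

    inactive_max: float = 0.0
    active_min: float = 55.0

    def __post_init__(self) -> None:
        if not self.inactive_max < self.active_min:
            raise ValueError("inactive_max must be below active_min")


DEFAULT_THRESHOLDS = StateThresholds()


def classify(value: float, thresholds: StateThresholds = DEFAULT_THRESHOLDS) -> str:
    """State label for one index value.

    Strictly below ``inactive_max`` -> "inactive"; strictly above
    ``active_min`` -> "active"; everything in between, including the
    threshold values themselves, -> "partial" (so the three intervals
    partition the real line).
    """
    if isinstance(value, (np.ndarray, list, tuple)):
        return np.array([classify(v, thresholds) for v in np.asarray(value).ravel()])
    if not math.isfinite(value):
        raise ValueError(f"cannot classify non-finite index value {value!r}")
    if value < thresholds.inactive_max:
        return "inactive"
    if value > thresholds.active_min:
        return "active"
    return "partial"


@dataclass
class IndexSeries:
    """Per-frame activation-index values with times and state labels."""

    values: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    thresholds: StateThresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype="U8")
        if not (len(self.values) == len(self.times) == len(self.labels)):
            raise ValueError("values, times and labels must have equal length")

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        times: np.ndarray | None = None,
        thresholds: StateThresholds = DEFAULT_THRESHOLDS,
    ) -> "IndexSeries":
        values = np.asarray(values, dtype=np.float64)
        if times is None:
            times = np.arange(len(values), dtype=np.float64)
        labels = np.array([classify(v, thresholds) for v in values])
        return cls(values=values, times=times, labels=labels, thresholds=thresholds)

    def __len__(self) -> int:
        return len(self.values)


def compute_index(
    traj: Trajectory,
    model: ActivationModel,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> IndexSeries:
    """Evaluate the activation index on every frame of a trajectory."""
    pairs = model.resolve(traj.structure)
    idx_a = np.array([a for a, _ in pairs])
    idx_b = np.array([b for _, b in pairs])
    diff = traj.coords[:, idx_a] - traj.coords[:, idx_b]   # (frames, desc, 3)
    dists = np.linalg.norm(diff, axis=2)
    values = model.intercept + dists @ model.coefficients
    return IndexSeries.from_values(values, times=traj.times, thresholds=thresholds)


def occupancy(series: IndexSeries) -> dict[str, float]:
    """Fraction of frames per state; the three fractions sum to 1."""
    if len(series) == 0:
        raise ValueError("cannot compute occupancy of an empty series")
    n = len(series)
    return {s: float(np.sum(series.labels == s)) / n for s in STATE_LABELS}


@dataclass
class StateDistribution:
    """Histogram + KDE summary of an index (or distance) series."""

    bin_edges: np.ndarray
    densities: np.ndarray
    kde_grid: np.ndarray | None
    kde_densities: np.ndarray | None
    modes: np.ndarray
    mean: float
    sd: float               # blocking SD of the mean
    sd_err: float
    sd_converged: bool

    @property
    def primary_mode(self) -> float:
        if len(self.modes) == 0:
            raise ValueError("no modes detected")
        if self.kde_densities is None:
            return float(self.modes[0])
        heights = np.interp(self.modes, self.kde_grid, self.kde_densities)
        return float(self.modes[int(np.argmax(heights))])


def _kde_modes(grid: np.ndarray, dens: np.ndarray, prominence: float) -> np.ndarray:
    """Locations of KDE local maxima at >= prominence * global max height."""
    if len(dens) < 3:
        return np.array([])
    maxima = list(argrelextrema(dens, np.greater)[0])
    # include plateau edges / boundary maxima
    if dens[0] > dens[1]:
        maxima.insert(0, 0)
    if dens[-1] > dens[-2]:
        maxima.append(len(dens) - 1)
    if not maxima:
        return np.array([])
    cutoff = prominence * float(dens.max())
    locs = [grid[i] for i in maxima if dens[i] >= cutoff]
    return np.array(sorted(locs))


def distribution(
    series: IndexSeries | np.ndarray,
    bins: int = 60,
    bandwidth: float | str | None = None,
    grid_points: int = 512,
    prominence: float = 0.05,
) -> StateDistribution:
    """Normalized histogram + Gaussian KDE summary with blocking SD.

    The histogram spans [min, max] padded by 5% on each side; the KDE
    uses Silverman's bandwidth rule unless overridden.  The SD of the
    mean and its error come from the blocking curve's plateau (frames
    are autocorrelated, so the naive SD of the mean is not reported).
    A constant series yields a histogram-only summary with a warning.
    """
    values = series.values if isinstance(series, IndexSeries) else np.asarray(series, float)
    if len(values) < 50:
        raise ValueError("distribution requires at least 50 frames")
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    pad = 0.05 * span if span > 0 else max(abs(lo) * 0.05, 0.5)
    edges = np.linspace(lo - pad, hi + pad, bins + 1)
    dens, edges = np.histogram(values, bins=edges, density=True)

    curve = blocking_curve(values)
    _, sd, converged = plateau(curve)

    if span <= 0:
        logger.warning("constant series: KDE skipped, histogram-only summary")
        return StateDistribution(
            bin_edges=edges, densities=dens, kde_grid=None, kde_densities=None,
            modes=np.array([lo]), mean=lo, sd=sd, sd_err=0.0, sd_converged=converged,
        )

    kde = gaussian_kde(values, bw_method=bandwidth if bandwidth is not None else "silverman")
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    kde_dens = kde(grid)
    modes = _kde_modes(grid, kde_dens, prominence)
    lstar_idx = int(np.argmin(np.abs(curve.sd - sd)))
    return StateDistribution(
        bin_edges=edges, densities=dens, kde_grid=grid, kde_densities=kde_dens,
        modes=modes, mean=float(values.mean()),
        sd=sd, sd_err=float(curve.sd_err[lstar_idx]), sd_converged=converged,
    )


def detect_modes(dist: StateDistribution, prominence: float = 0.05) -> np.ndarray:
    """KDE local maxima with height >= prominence * global maximum, sorted."""
    if dist.kde_densities is None:
        raise ValueError("distribution has no KDE (constant series?)")
    return _kde_modes(dist.kde_grid, dist.kde_densities, prominence)


def calibrated_model(
    structure_active: Structure,
    structure_inactive: Structure,
    anchor_pairs: list[tuple[tuple[int, str], tuple[int, str]]],
    active_value: float = 75.0,
    inactive_value: float = -25.0,
) -> ActivationModel:
    """Activation model with prescribed index values at two reference states.

    Coefficients follow the matched-filter direction (proportional to
    the active-minus-inactive distance change of each anchor pair) and
    are scaled, with the intercept, so the noiseless active and inactive
    geometries map exactly to ``active_value`` and ``inactive_value``.
    Used to drive the synthetic generator's ground-truth recovery tests.
    """
    descriptors = [(ra, aa, rb, ab) for (ra, aa), (rb, ab) in anchor_pairs]
    d_act, d_ina = [], []
    for (ra, aa), (rb, ab) in anchor_pairs:
        for struct, acc in ((structure_active, d_act), (structure_inactive, d_ina)):
            p = struct.coords[struct.atom_index(ra, aa)]
            q = struct.coords[struct.atom_index(rb, ab)]
            acc.append(float(np.linalg.norm(p - q)))
    d_act, d_ina = np.array(d_act), np.array(d_ina)
    delta = d_act - d_ina
    denom = float(delta @ delta)
    if denom < 1e-12:
        raise ValueError("anchor pairs do not separate the two states")
    alpha = (active_value - inactive_value) / denom
    coefficients = alpha * delta
    intercept = active_value - float(coefficients @ d_act)
    return ActivationModel(descriptors, coefficients, intercept)
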