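"""Dose-response and densitometry statistics for receptor-rescue assays.

Covers the quantitative layer of a pharmacoperone study's in-vitro
readouts: four-parameter logistic (4PL) dose-response fitting with EC50
and standard errors, trapezoidal AUC of stimulation curves, Holm
step-down multiple-testing adjustment, Welch contrasts of
mature/immature (M/I) receptor-band ratios, one-way ANOVA with
Holm-adjusted pairwise tests, and a synthetic assay generator for
parameter-recovery testing.

The 4PL model, with dose d:

    r(d) = bottom + (top - bottom) / (1 + (EC50 / d) ** hill)

EC50 is the dose at half-maximal response; hill sets the steepness.
Zero doses are handled by the parameterization's limit (r -> bottom for
hill > 0), not by dropping points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class DoseResponse:
    """Dose grid plus replicate responses (replicates x doses)."""

    doses: np.ndarray
    responses: np.ndarray   # shape (n_replicates, n_doses)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.float64)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=np.float64))
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(self.doses) < 0):
            raise ValueError("doses must be sorted ascending")
        if self.responses.shape[1] != len(self.doses):
            raise ValueError(
                f"responses have {self.responses.shape[1]} dose columns, "
                f"expected {len(self.doses)}"
            )

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose, response) pairs with replicates stacked."""
        n_rep = self.responses.shape[0]
        return np.tile(self.doses, n_rep), self.responses.ravel()


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with standard errors."""

    bottom: float
    top: float
    ec50: float
    hill: float
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __call__(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)


def four_pl(dose, bottom: float, top: float, ec50: float, hill: float):
    """4PL response; dose 0 maps to ``bottom`` (hill > 0 limit)."""
    dose = np.asarray(dose, dtype=np.float64)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(dose > 0, ec50 / np.where(dose > 0, dose, 1.0), np.inf)
        out = bottom + (top - bottom) / (1.0 + ratio**hill)
    return out if out.ndim else float(out)


def _fit_once(x, y, p0) -> tuple[np.ndarray, np.ndarray]:
    # fit on log10(EC50) internally: enforces EC50 > 0 and conditions the fit
    def model(d, bottom, top, log_ec50, hill):
        return four_pl(d, bottom, top, 10.0**log_ec50, hill)

    import warnings

    with warnings.catch_warnings():
        # zero-residual fits legitimately yield a singular covariance
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(
            model, x, y,
            p0=[p0[0], p0[1], math.log10(p0[2]), p0[3]],
            maxfev=20000,
        )
    return popt, pcov


def fit_4pl(data: DoseResponse) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    Starting points combine hill in {0.5, 1, 2} with EC50 at the dose
    quantiles; the best converged least-squares solution wins.  If every
    start fails (e.g. non-monotone data), the fit is returned with
    ``converged=False`` and NaN parameters — the flag is honest, never
    papered over.
    """
    positive = data.doses[data.doses > 0]
    if len(np.unique(data.doses)) < 4:
        raise ValueError("4PL fitting needs at least 4 distinct doses")
    x, y = data.flat()
    bottom0, top0 = float(np.min(y)), float(np.max(y))
    if top0 <= bottom0:
        top0 = bottom0 + 1.0
    ec50_starts = np.quantile(positive, [0.25, 0.5, 0.75])
    best, best_cost, best_cov = None, np.inf, None
    for hill0 in (0.5, 1.0, 2.0):
        for ec0 in ec50_starts:
            try:
                popt, pcov = _fit_once(x, y, (bottom0, top0, float(ec0), hill0))
            except (RuntimeError, optimize.OptimizeWarning, ValueError):
                continue
            resid = y - four_pl(x, popt[0], popt[1], 10.0**popt[2], popt[3])
            cost = float(resid @ resid)
            if cost < best_cost:
                best, best_cost, best_cov = popt, cost, pcov
    if best is None:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, {}, converged=False)
    bottom, top, log_ec50, hill = best
    ec50 = 10.0**log_ec50
    se = {}
    if best_cov is not None and np.all(np.isfinite(best_cov)):
        perr = np.sqrt(np.clip(np.diag(best_cov), 0.0, None))
        # delta method: SE(EC50) = ln(10) * EC50 * SE(log10 EC50)
        se = {
            "bottom": float(perr[0]),
            "top": float(perr[1]),
            "ec50": float(math.log(10.0) * ec50 * perr[2]),
            "hill": float(perr[3]),
        }
    if top < bottom:  # canonical orientation: top >= bottom
        bottom, top = top, bottom
        hill = -hill
    return FourPLFit(float(bottom), float(top), float(ec50), float(hill), se, True)


def auc_trapezoid(x: np.ndarray, y: np.ndarray) -> float:
    """Composite trapezoid-rule area under y(x); x strictly increasing."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    return float(np.trapezoid(y, x))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotone non-decreasing adjusted values, cap at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


@dataclass
class DensitometryRecord:
    """One western-blot densitometry measurement.

    The M/I ratio (mature ~80 kDa band over immature <=75 kDa band) is
    the plasma-membrane-expression index; it is derived on construction
    when not supplied.
    """

    variant: str
    condition: str            # "vehicle" | "treated"
    mature: float
    immature: float
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.mature < 0 or self.immature < 0:
            raise ValueError("band intensities must be non-negative")
        if self.ratio is None:
            if self.immature <= 0:
                raise ValueError("immature intensity must be positive to form M/I ratio")
            self.ratio = self.mature / self.immature


def mi_ratio_contrast(
    records: list[DensitometryRecord],
    treated: str = "treated",
    vehicle: str = "vehicle",
) -> dict[str, float]:
    """Fold change in M/I ratio (treated / vehicle) with Welch t-test p.

    Welch's unequal-variance unpaired t-test is used; each condition
    needs at least 2 replicate records.
    """
    groups = {treated: [], vehicle: []}
    for rec in records:
        if rec.condition in groups:
            groups[rec.condition].append(rec.ratio)
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} has {len(vals)} records; need >= 2")
    rt = np.asarray(groups[treated], float)
    rv = np.asarray(groups[vehicle], float)
    tstat, p = stats.ttest_ind(rt, rv, equal_var=False)
    return {
        "fold": float(rt.mean() / rv.mean()),
        "t": float(tstat),
        "p": float(p),
        "n_treated": len(rt),
        "n_vehicle": len(rv),
    }


def anova_pairwise(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus Holm-adjusted pairwise Welch t-tests.

    Routine frequentist machinery for multi-condition reporter assays:
    the global F-test asks whether any condition differs; the pairwise
    Welch contrasts, Holm-adjusted within the family, say which.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    f, p = stats.f_oneway(*arrays.values())
    names = list(arrays)
    pairs, raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            _, pij = stats.ttest_ind(arrays[names[i]], arrays[names[j]], equal_var=False)
            pairs.append((names[i], names[j]))
            raw.append(float(pij))
    adjusted = holm_adjust(raw) if raw else np.array([])
    return {
        "anova_F": float(f),
        "anova_p": float(p),
        "pairwise": [
            {"a": a, "b": b, "p_raw": pr, "p_holm": float(pa)}
            for (a, b), pr, pa in zip(pairs, raw, adjusted)
        ],
    }


# ---------------------------------------------------------------------------
# Synthetic assay data
# ---------------------------------------------------------------------------

def simulate_assay(
    truth: FourPLFit,
    doses: np.ndarray,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> DoseResponse:
    """Dose-response data with multiplicative log-normal noise around a truth curve.

    Noise is mean-one log-normal with coefficient of variation ``cv``
    (sigma_ln = sqrt(ln(1 + cv²)), mean-corrected), so the expected
    response equals the truth curve at every dose.  Identical seeds give
    identical data.
    """
    if cv < 0:
        raise ValueError("noise CV must be non-negative")
    doses = np.asarray(doses, dtype=np.float64)
    rng = np.random.default_rng(seed)
    clean = truth(doses)
    if cv == 0:
        noise = np.ones((n_replicates, len(doses)))
    else:
        sigma = math.sqrt(math.log(1.0 + cv**2))
        noise = np.exp(
            rng.normal(0.0, sigma, size=(n_replicates, len(doses))) - sigma**2 / 2
        )
    return DoseResponse(doses=doses, responses=clean[None, :] * noise)


def simulate_densitometry(
    variant: str,
    vehicle_ratio: float = 1.0,
    fold: float = 1.6,
    cv: float = 0.10,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[DensitometryRecord]:
    """Paired vehicle/treated M/I-ratio records at a known true fold change.

    Band intensities are generated so that the expected M/I ratio is
    ``vehicle_ratio`` under vehicle and ``vehicle_ratio * fold`` after
    treatment, with mean-one log-normal noise of coefficient of
    variation ``cv`` on the mature band.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    records = []
    for cond, ratio in (("vehicle", vehicle_ratio), ("treated", vehicle_ratio * fold)):
        for _ in range(n_replicates):
            immature = 100.0
            noise = math.exp(rng.normal(0.0, sigma) - sigma**2 / 2) if sigma else 1.0
            mature = ratio * immature * noise
            records.append(DensitometryRecord(variant, cond, mature, immature))
    return records
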