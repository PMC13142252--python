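"""Blocking-average error estimation for correlated time series.

MD observables such as a per-frame activation index are strongly
autocorrelated, so the naive standard error of the mean underestimates
the true uncertainty.  The blocking (pair-averaging renormalization)
method repeatedly replaces the series by the means of consecutive
pairs; at each level the standard-deviation-of-the-mean estimate

    s_l = sqrt( var(x^(l)) / (n_l - 1) ),   e_l = s_l / sqrt(2 (n_l - 1))

is recorded (``var`` is the population variance of the blocked series).
Once the block length exceeds the correlation time the blocks are
effectively independent and s_l reaches a plateau, which is read off as
the converged error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: variance of the variance is undefined below this block count
MIN_BLOCKS = 4

#: number of trailing levels that must mutually agree before the
#: plateau is reported as converged (guards against spurious agreement
#: between the last, noisiest levels of a still-rising curve)
MIN_PLATEAU_SPAN = 3

#: a plateau starting where fewer than this many blocks remain is not
#: trusted: with so few blocks the error bars are wide enough to mask a
#: still-rising curve
MIN_CONVERGED_BLOCKS = 32


@dataclass
class BlockingCurve:
    """Per-level estimates from successive pair-averaging transforms."""

    n_blocks: np.ndarray   # series length at each level
    sd: np.ndarray         # SD-of-the-mean estimate s_l
    sd_err: np.ndarray     # error of the estimate e_l

    def __post_init__(self) -> None:
        self.n_blocks = np.asarray(self.n_blocks, dtype=np.int64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        self.sd_err = np.asarray(self.sd_err, dtype=np.float64)
        if not (len(self.n_blocks) == len(self.sd) == len(self.sd_err)):
            raise ValueError("level arrays must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("SD estimates must be non-negative")

    @property
    def n_levels(self) -> int:
        return len(self.sd)

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.n_levels)


def block_transform(series: np.ndarray) -> np.ndarray:
    """One pair-averaging step: x'_i = (x_{2i-1} + x_{2i}) / 2.

    A trailing unpaired element on odd-length input is dropped (the
    standard convention; averaging it into a triple would bias the
    block means).
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("series must be 1-D with at least 2 elements")
    n = len(series) // 2
    return 0.5 * (series[: 2 * n : 2] + series[1 : 2 * n : 2])


def blocking_curve(series: np.ndarray) -> BlockingCurve:
    """Full blocking curve: SD-of-mean estimate and its error per level.

    Levels run from the raw series (level 0) down to the last level with
    at least :data:`MIN_BLOCKS` blocks.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("series must be 1-D with at least 8 elements")
    n_blocks, sd, sd_err = [], [], []
    while len(x) >= MIN_BLOCKS:
        n = len(x)
        var = float(np.var(x))  # population variance of the blocked series
        s = np.sqrt(var / (n - 1))
        n_blocks.append(n)
        sd.append(s)
        sd_err.append(s / np.sqrt(2.0 * (n - 1)))
        if n // 2 < MIN_BLOCKS:
            break
        x = block_transform(x)
    return BlockingCurve(np.array(n_blocks), np.array(sd), np.array(sd_err))


def plateau(curve: BlockingCurve) -> tuple[int, float, bool]:
    """Locate the blocking plateau: (level, SD estimate, converged flag).

    For an autocorrelated series the estimates rise with level until the
    block length exceeds the correlation time, then scatter around a
    constant within their error bars.  The plateau level l* is therefore
    placed just after the last *significant rise* — the last pair of
    consecutive levels whose increase s_{l+1} - s_l exceeds the combined
    ±1 standard-error bars e_l + e_{l+1}.  (Testing for constancy of all
    later levels simultaneously is statistically self-defeating: at the
    true plateau the estimates scatter by exactly their error bars, so
    some pair among many levels always disagrees.)

    The curve is reported converged only when at least
    :data:`MIN_PLATEAU_SPAN` levels lie on the plateau; a curve still
    rising into its final, noisiest levels is flagged unconverged and
    the last estimate returned as a lower bound.
    """
    if curve.n_levels < 3:
        raise ValueError("plateau detection needs at least 3 levels")
    s, e = curve.sd, curve.sd_err
    lstar = 0
    for j in range(curve.n_levels - 1):
        if (s[j + 1] - s[j]) > (e[j] + e[j + 1]):
            lstar = j + 1
    converged = bool(
        (curve.n_levels - lstar) >= MIN_PLATEAU_SPAN
        and curve.n_blocks[lstar] >= MIN_CONVERGED_BLOCKS
    )
    return lstar, float(s[lstar]), converged
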