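"""Agreement and repeatability statistics for paired/repeated VOI measurements.

Implements the descriptive statistics used to validate quantitative maps
against reference values and across scan sessions:

* :func:`relative_difference` — percent difference vs a reference.
* :func:`bland_altman` — mean bias and 95% limits of agreement
  (bias +/- 1.96*SD of the percent differences), with the denominator either
  the reference series (phantom-vs-reference comparisons) or the pairwise
  mean (method-vs-method comparisons).
* :func:`repeatability` — coefficient of variation over repeated sessions
  with a 95% confidence interval by McKay's chi-square approximation, plus a
  five-number summary of the relative differences of each session against
  the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "RepeatabilityResult",
    "relative_difference",
    "bland_altman",
    "repeatability",
]


@dataclass
class AgreementResult:
    """Bland-Altman bias and limits of agreement (percent units)."""

    mean_bias_percent: float
    loa_low: float
    loa_high: float
    per_pair_differences: np.ndarray
    mode: str = "vs_reference"


@dataclass
class FiveNumberSummary:
    median: float
    q1: float
    q3: float
    min: float
    max: float

    @classmethod
    def from_series(cls, x: np.ndarray) -> "FiveNumberSummary":
        return cls(
            median=float(np.median(x)),
            q1=float(np.percentile(x, 25)),
            q3=float(np.percentile(x, 75)),
            min=float(np.min(x)),
            max=float(np.max(x)),
        )


@dataclass
class RepeatabilityResult:
    """Session-to-session CV with 95% CI and drift-vs-first summary."""

    cv_percent: float
    ci95_low: float
    ci95_high: float
    n_sessions: int
    relative_diffs_vs_first: FiveNumberSummary


def relative_difference(measured: float, reference: float) -> float:
    """100 * (measured - reference) / reference."""
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (measured - reference) / reference


def bland_altman(
    series_a,
    series_b,
    mode: str = "vs_reference",
) -> AgreementResult:
    """Bland-Altman agreement between two paired series, in percent.

    ``mode="vs_reference"`` divides each difference by the corresponding
    value of ``series_b`` (the reference); ``mode="vs_mean"`` divides by the
    pairwise mean, the symmetric convention for comparing two imperfect
    methods.  Limits of agreement are bias +/- 1.96*SD (n-1 denominator).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("at least 2 pairs are required")
    if mode == "vs_reference":
        denom = b
    elif mode == "vs_mean":
        denom = 0.5 * (a + b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(denom == 0):
        raise ValueError("zero denominator in percent-difference computation")
    diffs = 100.0 * (a - b) / denom
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        mean_bias_percent=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        per_pair_differences=diffs,
        mode=mode,
    )


def _mckay_ci(cv_fraction: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """McKay's approximate CI for a normal coefficient of variation.

    Based on the approximation that nu*K^2*(1+k^2)/(k^2*(1+K^2)) is
    chi-square with nu = n-1 degrees of freedom, solved for the population
    CV k at the two chi-square quantiles.
    """
    if cv_fraction == 0.0:
        return 0.0, 0.0
    nu = n - 1
    k = cv_fraction
    u_low = sps.chi2.ppf(1 - alpha / 2, nu)  # large quantile -> lower bound
    u_high = sps.chi2.ppf(alpha / 2, nu)

    def bound(u):
        inner = (u / nu) * (1.0 + k**2) - k**2
        if inner <= 0:
            return float("inf")
        return k / np.sqrt(inner)

    return bound(u_low), bound(u_high)


def repeatability(sessions) -> RepeatabilityResult | list[RepeatabilityResult]:
    """Repeatability of VOI means over scan sessions.

    ``sessions`` is either a 1-D array of per-session VOI means for one
    region, or a 2-D array (n_sessions, n_regions), in which case a list of
    per-region results is returned.  Session 1 (row 0) is the reference for
    the relative-difference summary; the CV is computed over all sessions.
    """
    x = np.asarray(sessions, dtype=float)
    if x.ndim == 2:
        return [repeatability(x[:, j]) for j in range(x.shape[1])]
    if x.ndim != 1:
        raise ValueError("sessions must be 1-D or 2-D")
    n = x.size
    if n < 2:
        raise ValueError("at least 2 sessions are required")
    if np.any(x == 0):
        raise ValueError("a session has zero mean; relative statistics undefined")
    mean = x.mean()
    sd = x.std(ddof=1)
    cv = sd / mean
    lo, hi = _mckay_ci(cv, n)
    rel = 100.0 * (x[1:] - x[0]) / x[0]
    return RepeatabilityResult(
        cv_percent=100.0 * cv,
        ci95_low=100.0 * lo,
        ci95_high=100.0 * hi,
        n_sessions=n,
        relative_diffs_vs_first=FiveNumberSummary.from_series(rel),
    )
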