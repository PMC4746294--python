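"""Outlier rejection, variance-homogeneity inference, and correlations.

The study's central inference is about *variance*: anodal DLPFC stimulation
reduced the between-subject spread of learning rates. Trial-wise variance
ratios use a two-sample F-test with asymmetric tail-appropriate critical
values; day-wise comparisons use Bartlett's test on per-subject day averages
to preserve sample independence.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataError


def reject_outliers(values: Sequence[float], k: float = 3.0):
    """Single-pass k-SD outlier rejection over the pooled trial distribution.

    Returns (kept values, boolean keep-mask aligned with the input). A
    zero-spread sample removes nothing (sd = 0 guard). Rejection is not
    iterated: the threshold uses the mean/SD of the full input once.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise DataError("need ≥ 3 values for outlier rejection")
    finite = np.isfinite(values)
    mean = values[finite].mean()
    sd = values[finite].std(ddof=1)
    if sd == 0.0:
        mask = finite.copy()
    else:
        mask = finite & (np.abs(values - mean) <= k * sd)
    return values[mask], mask


@dataclass(frozen=True)
class VarianceTestResult:
    """F or Bartlett χ² test outcome; ``direction`` names the smaller-variance
    sample; ``distance_from_null`` is the distance of F from 1 (F-test only)."""

    statistic: float
    df: tuple
    p: float
    direction: Optional[str] = None
    distance_from_null: Optional[float] = None
    degenerate: bool = False


def variance_ftest(sample_a: Sequence[float], sample_b: Sequence[float],
                   names: tuple[str, str] = ("a", "b")) -> VarianceTestResult:
    """Two-sample F-test for equal variances, F = s²_a / s²_b.

    The p-value is two-sided via the asymmetric F CDF appropriate to the
    degrees of freedom: p = 2·min(P(F ≤ f), P(F ≥ f)), capped at 1, so the
    same p results whichever sample is the numerator.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each sample needs ≥ 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    if vb == 0.0:
        return VarianceTestResult(float("inf"), (dfa, dfb), 0.0 if va > 0 else 1.0,
                                  direction=names[1] if va > 0 else None,
                                  degenerate=True)
    f = va / vb
    dist = stats.f(dfa, dfb)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return VarianceTestResult(
        statistic=float(f), df=(dfa, dfb), p=float(p),
        direction=names[0] if f < 1 else names[1],
        distance_from_null=float(f - 1.0),
    )


def bartlett(groups: Sequence[Sequence[float]],
             names: Sequence[str] | None = None) -> VarianceTestResult:
    """Bartlett's test of equal population variance across ≥ 2 groups.

    Inputs should be per-subject day averages (one value per subject) so the
    samples are independent. χ² has k−1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DataError("need ≥ 2 groups")
    if any(len(g) < 2 for g in groups):
        raise DataError("each group needs ≥ 2 subjects")
    stat, p = stats.bartlett(*groups)
    variances = [g.var(ddof=1) for g in groups]
    direction = None
    if names is not None:
        direction = names[int(np.argmin(variances))]
    return VarianceTestResult(statistic=float(stat), df=(len(groups) - 1,),
                              p=float(p), direction=direction)


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int
    tier: str  # "significant" | "trend" | "ns"


def correlate(x: Sequence[float], y: Sequence[float],
              alpha_strict: float = 0.001, alpha_trend: float = 0.05) -> CorrelationResult:
    """Pearson correlation over paired complete cases, tiered at a
    conservative α (significant) and a relaxed α (trend).

    The strict tier guards the large number of cross-modality comparisons
    (EEG × fNIRS × behaviour) without a formal family correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("x and y must pair up")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DataError("need ≥ 3 complete cases")
    r, p = stats.pearsonr(x, y)
    tier = "significant" if p < alpha_strict else ("trend" if p < alpha_trend else "ns")
    return CorrelationResult(float(r), float(p), len(x), tier)
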