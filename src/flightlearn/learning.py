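"""Learning-rate decomposition: overall, online, offline, and meta rates.

A performance series over the four training days is decomposed into the
overall OLS slope across all trials, per-day (online) slopes, day-boundary
(offline) gains between the last trial of one day and the first of the next,
and a meta rate — the slope of the interleaved online/offline rate sequence,
i.e. how fast the learning rates themselves change.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataError


class RateEstimate(NamedTuple):
    """OLS slope and its standard error (units: metric units per trial index)."""
    slope: float
    stderr: float


@dataclass
class LearningRateSet:
    """One metric's full decomposition for a subject or a group-average series."""
    overall: RateEstimate
    online: list          # one RateEstimate per day
    offline: list[float]  # one gain per day boundary (n_days − 1)
    meta: RateEstimate


def _ols(y: Sequence[float], x: Sequence[float] | None = None) -> RateEstimate:
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(1, len(y) + 1, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    keep = ~np.isnan(y)
    y, x = y[keep], x[keep]
    if len(y) < 2:
        raise DataError("need at least 2 non-missing points for a slope")
    if len(y) == 2:
        # slope is exact; linregress stderr would be 0/0
        return RateEstimate(float((y[1] - y[0]) / (x[1] - x[0])), float("nan"))
    if np.ptp(y) == 0.0:
        # constant series: zero slope, zero residuals (linregress yields NaN)
        return RateEstimate(0.0, 0.0)
    res = stats.linregress(x, y)
    return RateEstimate(float(res.slope), float(res.stderr))


def online_rate(series: Sequence[float], x: Sequence[float] | None = None) -> RateEstimate:
    """Within-day OLS slope over trial/block index (missing values dropped,
    indices preserved)."""
    return _ols(series, x)


def overall_rate(series: Sequence[float], x: Sequence[float] | None = None) -> RateEstimate:
    """OLS slope over the concatenated trial index across all days."""
    return _ols(series, x)


def offline_rate(last_of_prev_day: float, first_of_next_day: float) -> float:
    """Overnight gain: first trial of day n minus last trial of day n−1,
    treated as a slope over unit trial-index spacing."""
    return float(first_of_next_day - last_of_prev_day)


def interleave_rates(online: Sequence[float], offline: Sequence[float]) -> np.ndarray:
    """Temporal interleaving [on₁, off₁₂, on₂, off₂₃, …, onₙ]."""
    online = list(online)
    offline = list(offline)
    if len(offline) != len(online) - 1:
        raise DataError("need n_days − 1 offline rates for n_days online rates")
    out = []
    for i, on in enumerate(online):
        out.append(on)
        if i < len(offline):
            out.append(offline[i])
    return np.asarray(out, dtype=float)


def meta_rate(rate_series: Sequence[float]) -> RateEstimate:
    """Slope of the interleaved online/offline rate sequence over its
    temporal index: the rate of change of the learning rates."""
    return _ols(rate_series)


def decompose(series_by_day: Sequence[Sequence[float]]) -> LearningRateSet:
    """Full decomposition from per-day trial series (e.g. 4 days × 6 blocks).

    The overall slope runs over the concatenated trial index; online slopes
    are fit within each day; offline gains bridge day boundaries; the meta
    rate is fit to the interleaved online/offline sequence.
    """
    series_by_day = [np.asarray(s, dtype=float) for s in series_by_day]
    if len(series_by_day) < 2:
        raise DataError("need at least 2 days")
    concat = np.concatenate(series_by_day)
    online = [online_rate(s) for s in series_by_day]
    offline = [
        offline_rate(series_by_day[d][~np.isnan(series_by_day[d])][-1],
                     series_by_day[d + 1][~np.isnan(series_by_day[d + 1])][0])
        for d in range(len(series_by_day) - 1)
    ]
    inter = interleave_rates([r.slope for r in online], offline)
    return LearningRateSet(
        overall=overall_rate(concat),
        online=online,
        offline=offline,
        meta=meta_rate(inter),
    )


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int


def one_sample_test(rates: Sequence[float], popmean: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test of subject rates against zero (or
    ``popmean``). A degenerate all-equal sample at the null returns t=0, p=1."""
    rates = np.asarray(rates, dtype=float)
    rates = rates[~np.isnan(rates)]
    if len(rates) < 2:
        raise DataError("need ≥ 2 rates")
    if np.ptp(rates) == 0.0:
        if rates[0] == popmean:
            return TTestResult(0.0, 1.0, len(rates) - 1)
        return TTestResult(float("inf") * np.sign(rates[0] - popmean), 0.0, len(rates) - 1)
    t, p = stats.ttest_1samp(rates, popmean)
    return TTestResult(float(t), float(p), len(rates) - 1)


def paired_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed paired t-test between two rate conditions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise DataError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise DataError("need ≥ 2 pairs")
    if np.ptp(a - b) == 0.0:
        if a[0] == b[0]:
            return TTestResult(0.0, 1.0, len(a) - 1)
        return TTestResult(float("inf") * np.sign(a[0] - b[0]), 0.0, len(a) - 1)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), float(p), len(a) - 1)
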