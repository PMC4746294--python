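"""Landing-performance metrics from 10 Hz flight telemetry.

Five bespoke metrics score each easy-landing attempt against the autopilot
reference flight: touchdown g-force, summed 3-D path deviation, summed
vertical-speed deviation, vertical-speed variance, and the count of control
inputs (vertical-speed sign changes). Landings that run off the end of the
runway are "missed" and excluded from metric aggregation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError

FT_TO_M = 0.3048
EARTH_RADIUS_M = 6_371_000.0
G0 = 9.8  # m/s², the convention used for the g-force metric


@dataclass
class FlightTrace:
    """Telemetry for one landing attempt, sampled at 10 Hz.

    ``alt`` is feet above ground level; ``vspeed`` is signed ft/min
    (negative = descent). ``touchdown_index`` is the first sample with
    alt == 0, or None if the aircraft never touched down in the recording.
    """

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    alt: np.ndarray
    vspeed: np.ndarray
    touchdown_index: Optional[int] = None
    missed: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.alt = np.asarray(self.alt, dtype=float)
        self.vspeed = np.asarray(self.vspeed, dtype=float)
        n = len(self.t)
        for name in ("lat", "lon", "alt", "vspeed"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length differs from t")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise DataError("time stamps must be strictly increasing")
        if np.any(self.alt < -1e-9):
            raise DataError("altitude AGL must be ≥ 0")
        if self.touchdown_index is None and not self.missed:
            ground = np.flatnonzero(self.alt <= 0.0)
            self.touchdown_index = int(ground[0]) if ground.size else None

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class LandingMetrics:
    """The five per-trial landing metrics (NaN where a missed landing
    leaves a metric undefined)."""

    gforce: float
    path_deviation: float
    vspeed_deviation: float
    vspeed_variance: float
    control_inputs: int
    missed: bool = False

    def as_dict(self) -> dict:
        return {
            "gforce": float(self.gforce),
            "path_deviation_m": float(self.path_deviation),
            "vspeed_deviation": float(self.vspeed_deviation),
            "vspeed_variance": float(self.vspeed_variance),
            "control_inputs": int(self.control_inputs),
            "missed": bool(self.missed),
        }


def landing_gforce(trace: FlightTrace) -> float:
    """Landing-impact g: |d(vspeed)/dt| across touchdown, in units of 9.8 m/s².

    Central finite difference where both neighbours exist, one-sided at the
    trace edge. Vertical speed is converted ft/min → m/s before
    differentiating. Undefined (NaN) for missed landings.
    """
    if trace.missed or trace.touchdown_index is None:
        return float("nan")
    i = trace.touchdown_index
    v = trace.vspeed * FT_TO_M / 60.0  # m/s
    dt = trace.dt
    if 0 < i < len(v) - 1:
        accel = (v[i + 1] - v[i - 1]) / (2 * dt)
    elif i > 0:
        accel = (v[i] - v[i - 1]) / dt
    elif len(v) > 1:
        accel = (v[i + 1] - v[i]) / dt
    else:
        return float("nan")
    return abs(accel) / G0


def geodetic_to_cartesian(lat, lon, alt_ft, origin) -> np.ndarray:
    """Local tangent-plane East-North-Up coordinates in meters.

    Spherical Earth, R = 6,371,000 m; ``origin`` is (lat0, lon0) of the
    runway threshold. ``alt_ft`` (feet AGL) becomes the Up axis in meters.
    Sub-meter accuracy is ample at landing-approach scale.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    alt_ft = np.asarray(alt_ft, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise DataError("latitude out of range [-90, 90]")
    lat0, lon0 = origin
    x = EARTH_RADIUS_M * np.cos(np.deg2rad(lat0)) * np.deg2rad(lon - lon0)
    y = EARTH_RADIUS_M * np.deg2rad(lat - lat0)
    z = alt_ft * FT_TO_M
    return np.stack([x, y, z], axis=-1)


def _window_average(values: np.ndarray, n_out: int) -> np.ndarray:
    """Average ``values`` over ``n_out`` near-equal contiguous chunks."""
    chunks = np.array_split(values, n_out, axis=0)
    return np.stack([c.mean(axis=0) for c in chunks])


def align_traces(a: np.ndarray, b: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample two sample series to a common length by moving-window averaging.

    The common length is min(len(a), len(b)) // window windows; each trace is
    split into that many contiguous chunks over its own full extent and
    chunk-averaged, which both resamples and time-aligns traces of unequal
    length. window=1 on equal-length traces is the identity.
    """
    n_out = min(len(a), len(b)) // window
    if n_out < 1:
        raise DataError("trace shorter than the averaging window")
    return _window_average(np.asarray(a, float), n_out), _window_average(
        np.asarray(b, float), n_out)


def path_deviation(subject: FlightTrace, autopilot: FlightTrace,
                   window: int = 10, origin=None) -> float:
    """Summed 3-D Euclidean distance (m) between aligned subject and
    autopilot flight paths, Σ√(Δx²+Δy²+Δz²) over window-averaged samples."""
    if origin is None:
        origin = (autopilot.lat[-1], autopilot.lon[-1])
    ps = geodetic_to_cartesian(subject.lat, subject.lon, subject.alt, origin)
    pa = geodetic_to_cartesian(autopilot.lat, autopilot.lon, autopilot.alt, origin)
    ps_w, pa_w = align_traces(ps, pa, window)
    return float(np.sum(np.linalg.norm(ps_w - pa_w, axis=1)))


def vspeed_deviation(subject: FlightTrace, autopilot: FlightTrace,
                     window: int = 10) -> float:
    """Summed absolute vertical-speed difference (ft/min) over aligned samples.

    Absolute differences are used: signed sums could cancel and a better
    landing must score lower.
    """
    vs, va = align_traces(subject.vspeed, autopilot.vspeed, window)
    return float(np.sum(np.abs(vs - va)))


def vspeed_variance(trace: FlightTrace) -> float:
    """Sample variance (ddof=1) of vertical speed from the start of the
    recording to touchdown (whole trace if no touchdown)."""
    stop = trace.touchdown_index + 1 if trace.touchdown_index is not None else len(trace)
    v = trace.vspeed[:stop]
    if len(v) < 2:
        return 0.0
    return float(np.var(v, ddof=1))


def control_inputs(trace: FlightTrace) -> int:
    """Number of sign changes in vertical speed over the landing period.

    Zero samples inherit the previous nonzero sign (hysteresis), so a
    noise-free hold at exactly 0 ft/min counts no input.
    """
    s = np.sign(trace.vspeed)
    nz = s[s != 0]
    if nz.size < 2:
        return 0
    return int(np.sum(nz[1:] != nz[:-1]))


def classify_missed(trace: FlightTrace, runway_extent_m: float,
                    origin, bearing_deg: float = 0.0) -> bool:
    """True iff the attempt must be scored as a missed landing.

    A landing is missed when there is no touchdown, or the touchdown point
    lies beyond the terminal end of the runway. ``origin`` is the runway
    threshold (lat, lon); ``bearing_deg`` the runway heading measured from
    North; ``runway_extent_m`` its length. A touchdown exactly at the
    terminal sample is not missed (inclusive boundary).
    """
    if trace.touchdown_index is None:
        return True
    i = trace.touchdown_index
    p = geodetic_to_cartesian(trace.lat[i], trace.lon[i], 0.0, origin)
    b = np.deg2rad(bearing_deg)
    along = p[0] * np.sin(b) + p[1] * np.cos(b)
    return bool(along > runway_extent_m)


def compute_metrics(subject: FlightTrace, autopilot: FlightTrace,
                    window: int = 10) -> LandingMetrics:
    """All five metrics for one attempt; path/vspeed deviations and g-force
    are NaN for missed landings."""
    if subject.missed or subject.touchdown_index is None:
        return LandingMetrics(float("nan"), float("nan"), float("nan"),
                              vspeed_variance(subject), control_inputs(subject),
                              missed=True)
    return LandingMetrics(
        gforce=landing_gforce(subject),
        path_deviation=path_deviation(subject, autopilot, window=window),
        vspeed_deviation=vspeed_deviation(subject, autopilot, window=window),
        vspeed_variance=vspeed_variance(subject),
        control_inputs=control_inputs(subject),
        missed=False,
    )


def metrics_table(trials: list[tuple[dict, FlightTrace]], autopilot: FlightTrace,
                  window: int = 10) -> pd.DataFrame:
    """Per-trial metric table. ``trials`` pairs a key dict (subject, group,
    day, trial, …) with each trace."""
    rows = []
    for keys, trace in trials:
        row = dict(keys)
        row.update(compute_metrics(trace, autopilot, window=window).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
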