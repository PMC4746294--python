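"""Synthetic four-group × four-day study generator.

Emulates every modality the analysis consumes — autopilot-referenced flight
telemetry (10 Hz), adaptive n-back trial logs, multichannel EEG (500 Hz), and
dual-wavelength fNIRS optical densities (8 Hz) — with the cohort structure of
the training study (DLPFC stim n=7, DLPFC sham n=7, M1 stim n=10, M1 sham
n=8; 4 days; 6 n-back blocks and 5 easy landings per day) and configurable
ground-truth effects: shrunken between-subject learning-rate variance under
DLPFC stimulation, a midline-frontal theta power increase across days, and a
DLPFC Hboxy decrease from day 1 to day 4. Every generated effect parameter is
returned alongside the data so downstream stages can be tested for recovery.

Neural records are generated lazily from per-record seeds derived from the
study seed, so a full 32-subject study stays lightweight in memory while
remaining byte-deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import (EffectConfig, StudyDesign, load_layout)
from .eeg_spectral import EEGRecord
from .errors import ConfigurationError, DataError
from .flight_metrics import FT_TO_M, FlightTrace
from .fnirs import (ChannelMap, ChromophoreSeries, ExtinctionModel,
                    OpticalDensityRecord, canonical_hrf, forward_od)
from .nback import NBackBlock, NBackConfig, NBackLog, adaptive_update

TASKS = ("nback", "landing")

#: fNIRS source-detector pairs of the study montage (10 per ROI).
M1_FNIRS_CHANNELS = ["FC3-FCC5h", "FC3-FCC3h", "C5-FCC5h", "C3-FCC5h", "C3-FCC3h",
                     "C1-FCC3h", "C5-CCP5h", "C3-CCP5h", "C3-CCP3h", "C1-CCP3h"]
DLPFC_FNIRS_CHANNELS = ["AFF6h-AFF2h", "AFF6h-F4", "F2-AFF2h", "F2-FC2", "F2-FFC4h",
                        "FFC6h-F4", "FFC6h-FFT8h", "FFC6h-FFC4h", "FC4-FFC4h", "FC4-F4"]


def default_channel_map(distance_cm: float = 3.0) -> ChannelMap:
    """The study's 20-channel montage: 10 channels over left M1 and 10 over
    right DLPFC, all within the ≤ 3.5 cm source-detector separation."""
    channels = M1_FNIRS_CHANNELS + DLPFC_FNIRS_CHANNELS
    return ChannelMap(
        channels=channels,
        distance_cm={ch: distance_cm for ch in channels},
        roi={ch: ("M1" if ch in M1_FNIRS_CHANNELS else "DLPFC") for ch in channels},
    )


# ---------------------------------------------------------------------------
# Flight telemetry
# ---------------------------------------------------------------------------

def autopilot_reference(alt0_ft: float = 800.0, vspeed_ftmin: float = -600.0,
                        flare_s: float = 5.0, fs: float = 10.0,
                        origin: tuple[float, float] = (47.46, -122.31),
                        ground_speed_mps: float = 65.0) -> FlightTrace:
    """The ideal autopilot landing: constant descent (default −600 ft/min)
    with vertical speed changing only in the final ``flare_s`` seconds, a
    single nose-flare zero crossing ~1 s before touchdown, and touchdown at
    the runway threshold (``origin``).

    Altitude integrates vertical speed up to flare onset, then eases linearly
    to 0 over the final second (ground-effect settling as 10 Hz telemetry
    records it).
    """
    dt = 1.0 / fs
    # final second: nose flare — vspeed crosses zero exactly once, then holds 0
    flare_blip = np.array([20.0, 15.0, 10.0, 6.0, 3.0, 1.0, 0.0, 0.0, 0.0, 0.0])
    n_blip = len(flare_blip)
    n_ramp = int(round((flare_s - 1.0) * fs))
    ramp = np.linspace(vspeed_ftmin, -60.0, n_ramp)
    ramp_drop = -np.sum(ramp) * dt / 60.0
    h_flare = 2.0  # ft remaining at flare onset
    steady_drop = alt0_ft - ramp_drop - h_flare
    n_steady = max(int(round(steady_drop / (-vspeed_ftmin * dt / 60.0))), 1)
    vspeed = np.concatenate([np.full(n_steady, vspeed_ftmin), ramp, flare_blip])
    n = len(vspeed)

    alt = np.empty(n)
    alt[0] = alt0_ft
    for k in range(n_steady + n_ramp - 1):
        alt[k + 1] = alt[k] + vspeed[k] * dt / 60.0
    alt[n_steady + n_ramp - 1:] = np.linspace(alt[n_steady + n_ramp - 1], 0.0,
                                              n - (n_steady + n_ramp) + 1)
    alt = np.maximum(alt, 0.0)
    alt[-1] = 0.0

    t = np.arange(n) * dt
    covered = ground_speed_mps * t
    northing = covered - covered[-1]          # touches down at the origin
    lat = origin[0] + northing / 111_195.0
    lon = np.full(n, origin[1])
    return FlightTrace(t=t, lat=lat, lon=lon, alt=alt, vspeed=vspeed,
                       touchdown_index=n - 1)


def generate_flight_trace(skill: float, reference: FlightTrace,
                          rng: np.random.Generator,
                          vspeed_noise_sd: float = 120.0,
                          drift_noise_m: float = 25.0,
                          alt_noise_ft: float = 15.0,
                          impact_sd: float = 250.0,
                          miss_prob: float = 0.0) -> FlightTrace:
    """One subject landing attempt: the autopilot reference perturbed by
    AR(1) vertical-speed noise, lateral alignment drift, altitude spread, and
    touchdown impact dynamics, all scaled by 1/skill. skill → ∞ returns the
    reference exactly. Missed landings (Bernoulli ``miss_prob``) never touch
    down and overshoot the runway.
    """
    if np.any(np.diff(reference.t) <= 0):
        raise DataError("reference time stamps must be strictly increasing")
    scale = 0.0 if np.isinf(skill) else 1.0 / skill
    n = len(reference)
    missed = bool(scale > 0 and rng.random() < miss_prob)

    def ar1(sd, phi=0.92):
        if sd == 0:
            return np.zeros(n)
        innov = rng.normal(0.0, sd * math.sqrt(1 - phi ** 2), size=n)
        innov[0] /= math.sqrt(1 - phi ** 2)  # stationary start
        from scipy.signal import lfilter
        return lfilter([1.0], [1.0, -phi], innov)

    vspeed = reference.vspeed + ar1(vspeed_noise_sd * scale)
    envelope = reference.alt / max(reference.alt[0], 1.0)
    alt = reference.alt + ar1(alt_noise_ft * scale) * envelope
    lat = reference.lat + ar1(drift_noise_m * scale) / 111_195.0
    lon = reference.lon + ar1(drift_noise_m * scale) / (
        111_195.0 * math.cos(math.radians(reference.lat[0])))

    if missed:
        # floats past the threshold without touching down
        alt = np.maximum(alt, 20.0 + 10.0 * envelope)
        return FlightTrace(t=reference.t.copy(), lat=lat, lon=lon, alt=alt,
                           vspeed=vspeed, touchdown_index=None, missed=True)

    td = reference.touchdown_index if reference.touchdown_index is not None else n - 1
    alt[:td] = np.maximum(alt[:td], 0.1)
    alt[td:] = 0.0
    if scale > 0 and td >= 1:
        # touchdown impact: residual sink rate arrested over one sample
        vspeed[td - 1] = -abs(rng.normal(0.0, impact_sd * scale)) - 20.0
        vspeed[td] = 0.0
    return FlightTrace(t=reference.t.copy(), lat=lat, lon=lon, alt=alt,
                       vspeed=vspeed, touchdown_index=int(td))


# ---------------------------------------------------------------------------
# n-back logs
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _ability_for_target(p: float, n_level: int, width: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return n_level + width * math.log(p / (1 - p))


def generate_nback_log(ability: float | None, design: StudyDesign,
                       rng: np.random.Generator,
                       config: NBackConfig | None = None,
                       target_scaled: np.ndarray | None = None,
                       subject: str = "S00", width: float = 0.5) -> NBackLog:
    """Simulate one subject's adaptive n-back sessions.

    Per-trial correctness follows a logistic accuracy model in (N − ability):
    p = σ((ability − N)/width). Either a constant ``ability`` is given, or
    ``target_scaled`` — an (n_days × n_blocks) array of target scaled
    accuracies — from which the block ability is derived by inverting the
    logistic at the current level, so the expected scaled accuracy equals the
    target regardless of level transitions. The N level starts at 1 on day 1
    and evolves by the adaptive rule, carrying across days.
    """
    config = config or NBackConfig()
    if (ability is None) == (target_scaled is None):
        raise ConfigurationError("give exactly one of ability or target_scaled")
    blocks = []
    n_level = config.n_min
    n_trials = design.n_nback_trials_per_block
    for day in range(1, design.n_days + 1):
        for b in range(design.n_nback_blocks_per_day):
            if target_scaled is not None:
                s = float(target_scaled[day - 1, b])
                p = float(np.clip(s / (100.0 * config.weight(n_level)), 0.0, 1.0))
                a = _ability_for_target(p, n_level, width)
            else:
                a = float(ability)
            p_trial = float(_logistic((a - n_level) / width))
            block = NBackBlock(
                block_index=(day - 1) * design.n_nback_blocks_per_day + b + 1,
                day=day, n_level=n_level,
                position_correct=rng.random(n_trials) < p_trial,
                image_correct=rng.random(n_trials) < p_trial,
            )
            blocks.append(block)
            n_level = adaptive_update(block.raw_accuracy, n_level, config)
    return NBackLog(subject=subject, blocks=blocks)


def nback_target_line(start: float, online_rate: float, offline_gains: np.ndarray,
                      design: StudyDesign) -> np.ndarray:
    """(n_days × n_blocks) target scaled-accuracy grid: within-day slope
    ``online_rate`` per block, day boundaries stepped by ``offline_gains``."""
    n_b = design.n_nback_blocks_per_day
    grid = np.empty((design.n_days, n_b))
    day_start = start
    for d in range(design.n_days):
        grid[d] = day_start + online_rate * np.arange(n_b)
        if d < design.n_days - 1:
            day_start = grid[d, -1] + offline_gains[d]
    return grid


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float,
                sd: float) -> np.ndarray:
    """1/f-amplitude noise, scaled to per-channel standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n_ch, n_samp))
    white = rng.normal(size=(n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n_samp, axis=-1)
    return pink / pink.std(axis=-1, keepdims=True) * sd


def generate_eeg(ch_names: list[str], theta_band_power: float,
                 alpha_band_power: float, rng: np.random.Generator,
                 fs: float = 500.0, duration_s: float = 30.0,
                 noise_sd: float = 0.5, task: str = "nback",
                 mft_channels: tuple[str, str] = ("Fz", "FC1")) -> EEGRecord:
    """Continuous multichannel EEG: pink noise plus band-limited oscillations.

    ``theta_band_power`` is the injected band-mean theta power (μV²) at the
    midline-frontal channels (6 Hz oscillation, frontal topography);
    ``alpha_band_power`` the alpha power at parietal/occipital channels
    (10 Hz). A 1-s Hann epoch concentrates a sinusoid of amplitude a into
    total power a²/2 across the band's integer bins, so the band-*mean* is
    a²/(2·n_bins) and amplitudes are set to √(2·n_bins·power) — n_bins = 4
    for theta (4–7 Hz), 5 for alpha (8–12 Hz).
    """
    n_samp = int(round(duration_s * fs))
    n_ch = len(ch_names)
    data = _pink_noise(rng, n_ch, n_samp, fs, noise_sd)
    t = np.arange(n_samp) / fs

    frontal = {"Fz", "FC1", "FC2", "FCz", "F3", "F4", "Fp1", "Fp2", "F7", "F8"}
    parietal = {"Pz", "P3", "P4", "P7", "P8", "O1", "O2", "Oz", "CP1", "CP2"}

    def topo(ch, focus, members):
        if ch in focus:
            return 1.0
        return 0.3 if ch in members else 0.1

    a_theta = math.sqrt(2.0 * 4 * max(theta_band_power, 0.0))
    a_alpha = math.sqrt(2.0 * 5 * max(alpha_band_power, 0.0))
    ph_t, ph_a = rng.uniform(0, 2 * np.pi, size=2)
    theta_w = np.array([topo(c, set(mft_channels), frontal) for c in ch_names])
    alpha_w = np.array([topo(c, {"Pz", "P3", "P4"}, parietal) for c in ch_names])
    data += np.outer(theta_w, a_theta * np.sin(2 * np.pi * 6.0 * t + ph_t))
    data += np.outer(alpha_w, a_alpha * np.sin(2 * np.pi * 10.0 * t + ph_a))
    return EEGRecord(data=data, fs=fs, ch_names=list(ch_names),
                     segments=[(task, 0, n_samp)])


# ---------------------------------------------------------------------------
# fNIRS
# ---------------------------------------------------------------------------

@dataclass
class FnirsGroundTruth:
    conc: ChromophoreSeries
    onsets: np.ndarray       # s
    durations: np.ndarray    # s
    amplitude_mM: dict       # roi -> hboxy amplitude


def generate_fnirs(channel_map: ChannelMap, rng: np.random.Generator,
                   hboxy_amplitude_mM: dict[str, float],
                   optics: ExtinctionModel | None = None,
                   fs: float = 8.0, n_trials: int = 5, trial_s: float = 30.0,
                   rest_s: float = 30.0, od_noise_sd: float = 1e-4,
                   drift: bool = True, cardiac: bool = True,
                   deoxy_ratio: float = -0.3
                   ) -> tuple[OpticalDensityRecord, FnirsGroundTruth]:
    """Dual-wavelength optical densities from a forward MBLL model.

    True concentration changes are HRF-convolved task boxcars with per-ROI
    Hboxy amplitudes (mM; |Δc| should stay ≤ 0.05 mM) and Hbdeoxy =
    ``deoxy_ratio`` × Hboxy; the forward model adds sensor noise plus
    optional slow drift and a 1.2 Hz cardiac rhythm, which the 0.01–0.2 Hz
    band-pass stage is expected to remove.
    """
    optics = optics or ExtinctionModel()
    for roi, amp in hboxy_amplitude_mM.items():
        if abs(amp) > 0.05:
            raise ConfigurationError(f"|Δc| for {roi} exceeds 0.05 mM")
    period = trial_s + rest_s
    onsets = rest_s + np.arange(n_trials) * period
    n_samp = int(round((onsets[-1] + trial_s + rest_s) * fs))
    hrf = canonical_hrf(fs)
    box = np.zeros(n_samp)
    for on in onsets:
        box[int(on * fs):int((on + trial_s) * fs)] = 1.0
    resp = np.convolve(box, hrf)[:n_samp]

    n_ch = len(channel_map.channels)
    hboxy = np.zeros((n_samp, n_ch))
    for j, ch in enumerate(channel_map.channels):
        roi = channel_map.roi.get(ch, "M1")
        hboxy[:, j] = hboxy_amplitude_mM.get(roi, 0.0) * resp
    hbdeoxy = deoxy_ratio * hboxy
    truth = ChromophoreSeries(hboxy, hbdeoxy, fs, list(channel_map.channels))

    record = forward_od(truth, optics, channel_map)
    t = np.arange(n_samp) / fs
    for lam in record.od:
        od = record.od[lam]
        if od_noise_sd > 0:
            od += rng.normal(0.0, od_noise_sd, size=od.shape)
        if drift:
            amp = rng.uniform(2e-4, 5e-4, size=n_ch)
            phase = rng.uniform(0, 2 * np.pi, size=n_ch)
            od += amp * np.sin(2 * np.pi * 0.002 * t[:, None] + phase)
            od += rng.normal(0, 1e-4, size=n_ch) * (t[:, None] / t[-1])
        if cardiac:
            amp = rng.uniform(1e-4, 2e-4, size=n_ch)
            phase = rng.uniform(0, 2 * np.pi, size=n_ch)
            od += amp * np.sin(2 * np.pi * 1.2 * t[:, None] + phase)
    return record, FnirsGroundTruth(conc=truth, onsets=onsets,
                                    durations=np.full(n_trials, trial_s),
                                    amplitude_mM=dict(hboxy_amplitude_mM))


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A generated cohort: behavioral data materialised, neural records
    produced on demand (deterministically) via :meth:`eeg` and :meth:`fnirs`."""

    design: StudyDesign
    effects: EffectConfig
    seed: int
    subjects: pd.DataFrame
    autopilot: FlightTrace
    nback_logs: dict
    flight_traces: dict          # (subject, day) -> list[FlightTrace]
    ground_truth: dict
    channel_map: ChannelMap = field(default_factory=default_channel_map)
    eeg_duration_s: float = 30.0
    layout: pd.DataFrame = None

    def _record_rng(self, kind: int, subj_idx: int, day: int, task_idx: int):
        return np.random.default_rng(
            [self.seed % (2 ** 31), kind, subj_idx, day, task_idx])

    def eeg(self, subject: str, day: int, task: str = "nback") -> EEGRecord:
        info = self.ground_truth["subjects"][subject]
        rng = self._record_rng(1, info["index"], day, TASKS.index(task))
        theta = info["theta_power_by_day"][day - 1]
        return generate_eeg(list(self.layout["label"]), theta,
                            self.effects.alpha_base_power, rng,
                            duration_s=self.eeg_duration_s,
                            noise_sd=self.effects.eeg_noise_sd, task=task)

    def fnirs(self, subject: str, day: int, task: str = "landing"):
        info = self.ground_truth["subjects"][subject]
        rng = self._record_rng(2, info["index"], day, TASKS.index(task))
        group = info["group"]
        # linear day interpolation of the injected day-4 − day-1 DLPFC change
        d4_d1 = self.effects.dlpfc_hboxy_day4_minus_day1[group]
        base = 0.004
        frac = (day - 1) / (self.design.n_days - 1)
        amp = {"DLPFC": base + d4_d1 * frac, "M1": base}
        n_trials = (self.design.n_landings_per_day if task == "landing"
                    else self.design.n_nback_blocks_per_day)
        return generate_fnirs(self.channel_map, rng, amp, n_trials=n_trials,
                              od_noise_sd=self.effects.fnirs_od_noise_sd)


def generate_study(design: StudyDesign | None = None,
                   effects: EffectConfig | None = None,
                   seed: int | None = None) -> SyntheticStudy:
    """Generate the full study. Deterministic for a fixed seed; the returned
    ground truth holds every injected per-subject parameter (true online
    rates, skills, neural effect sizes) for recovery testing."""
    design = design or StudyDesign()
    effects = effects or EffectConfig()
    if seed is None:
        seed = design.seed
    root = np.random.default_rng([seed % (2 ** 31), 0])
    subjects = design.subject_table()
    autopilot = autopilot_reference()
    layout = load_layout()

    nback_logs = {}
    flight_traces = {}
    gt_subjects = {}
    for idx, row in subjects.iterrows():
        subj, group = row["subject"], row["group"]
        r = root.normal(effects.online_rate_mean[group], effects.rate_sd_for(group))
        offline = root.normal(effects.offline_gain_mean, effects.offline_gain_sd,
                              size=design.n_days - 1)
        start = effects.nback_start_scaled + root.normal(0.0, 2.0)
        targets = nback_target_line(start, r, offline, design)
        nback_logs[subj] = generate_nback_log(
            None, design, root, target_scaled=targets, subject=subj)

        base_skill = math.exp(root.normal(0.0, 0.3))
        skills = []
        for day in range(1, design.n_days + 1):
            skill = base_skill * (1.0 + 0.35 * (day - 1))
            skills.append(skill)
            miss = np.interp(day, [1, design.n_days],
                             [effects.missed_landing_rate_day1,
                              effects.missed_landing_rate_day4])
            flight_traces[(subj, day)] = [
                generate_flight_trace(
                    skill, autopilot, root,
                    vspeed_noise_sd=effects.flight_vspeed_noise_sd,
                    drift_noise_m=effects.flight_drift_noise_m,
                    miss_prob=miss)
                for _ in range(design.n_landings_per_day)
            ]

        theta_by_day = [effects.theta_base_power
                        + effects.mft_day_slope[group] * (day - 1)
                        for day in range(1, design.n_days + 1)]
        gt_subjects[subj] = {
            "index": int(idx), "group": group,
            "online_rate": float(r),
            "offline_gains": [float(o) for o in offline],
            "nback_start": float(start),
            "skill_by_day": [float(s) for s in skills],
            "theta_power_by_day": [float(p) for p in theta_by_day],
        }

    ground_truth = {
        "seed": int(seed),
        "online_rate_mean": dict(effects.online_rate_mean),
        "online_rate_sd_effective": {g: effects.rate_sd_for(g)
                                     for g, _ in design.groups},
        "variance_shrink_factor": dict(effects.variance_shrink_factor),
        "mft_day_slope": dict(effects.mft_day_slope),
        "dlpfc_hboxy_day4_minus_day1": dict(effects.dlpfc_hboxy_day4_minus_day1),
        "subjects": gt_subjects,
    }
    return SyntheticStudy(design=design, effects=effects, seed=int(seed),
                          subjects=subjects, autopilot=autopilot,
                          nback_logs=nback_logs, flight_traces=flight_traces,
                          ground_truth=ground_truth, layout=layout)
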