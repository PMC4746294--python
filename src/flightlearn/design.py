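"""Study design, effect configuration, and stimulation-montage types.

The default four-group design mirrors the between-subject structure of the
flight-simulator tDCS training study this package analyses: anodal stimulation
over right DLPFC or left M1, each with a matched sham group, across four
consecutive daily sessions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import ConfigurationError

GROUP_LABELS = ("DLPFC_stim", "DLPFC_sham", "M1_stim", "M1_sham")
STIM_GROUPS = ("DLPFC_stim", "M1_stim")

#: Published per-electrode currents (μA) for the two maximum-focality montages.
M1_MONTAGE_CURRENTS = {"CP1": 1244, "CP3": 745, "FP1": -417, "F8": -448, "F9": -1124}
DLPFC_MONTAGE_CURRENTS = {"F6": 1511, "FC6": 482, "AF8": -271, "AF4": -283, "FP2": -1439}


@dataclass(frozen=True)
class StimMontage:
    """High-definition tDCS montage: signed electrode currents in μA.

    Signed currents must sum to zero (charge conservation through the scalp).
    The total current and nominal current density are stored verbatim as
    configured; the printed 2 mA / 0.04 A/m^2 pair is not internally
    consistent with the stated electrode areas and is deliberately not
    reconciled here.
    """

    target: str
    electrode_currents: dict[str, float]
    total_current_mA: float = 2.0
    current_density_A_per_m2: float = 0.04

    def __post_init__(self) -> None:
        if self.target not in ("DLPFC", "M1"):
            raise ConfigurationError(f"unknown stimulation target {self.target!r}")
        if abs(sum(self.electrode_currents.values())) > 1e-9:
            raise ConfigurationError(
                "montage currents must sum to 0 μA, got "
                f"{sum(self.electrode_currents.values())}"
            )

    @property
    def anode_total_uA(self) -> float:
        return sum(c for c in self.electrode_currents.values() if c > 0)


def m1_montage() -> StimMontage:
    return StimMontage("M1", dict(M1_MONTAGE_CURRENTS))


def dlpfc_montage() -> StimMontage:
    return StimMontage("DLPFC", dict(DLPFC_MONTAGE_CURRENTS))


@dataclass(frozen=True)
class StudyDesign:
    """Four-group × four-day training design.

    Defaults reproduce the study cohort: DLPFC stim n=7, DLPFC sham n=7,
    M1 stim n=10, M1 sham n=8; 4 days; 6 n-back blocks of 20 trials and
    5 easy-landing attempts per day.
    """

    groups: tuple[tuple[str, int], ...] = (
        ("DLPFC_stim", 7),
        ("DLPFC_sham", 7),
        ("M1_stim", 10),
        ("M1_sham", 8),
    )
    n_days: int = 4
    n_nback_blocks_per_day: int = 6
    n_nback_trials_per_block: int = 20
    n_landings_per_day: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.groups:
            if label not in GROUP_LABELS:
                raise ConfigurationError(f"unknown group label {label!r}")
            if n < 1:
                raise ConfigurationError(f"group {label} must have ≥1 subject")
        if self.n_days < 2:
            raise ConfigurationError("need at least 2 days")
        for name in ("n_nback_blocks_per_day", "n_nback_trials_per_block",
                     "n_landings_per_day"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be ≥1")

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)

    def subject_table(self) -> pd.DataFrame:
        """One row per subject: subject id ('S01'…) and group label."""
        rows = []
        i = 0
        for label, n in self.groups:
            for _ in range(n):
                i += 1
                rows.append({"subject": f"S{i:02d}", "group": label})
        return pd.DataFrame(rows)


def _per_group(value, default):
    out = dict(default)
    if value is not None:
        for k in value:
            if k not in GROUP_LABELS:
                raise ConfigurationError(f"unknown group label {k!r}")
        out.update(value)
    return out


@dataclass
class EffectConfig:
    """Ground-truth effect sizes injected by the synthetic-data generator.

    Directions follow the study's summary of effects: reduced between-subject
    online-learning-rate variance under DLPFC stimulation, increased
    midline-frontal theta power, and decreased DLPFC Hboxy/Hbtot from day 1
    to day 4.

    Units: online rates are scaled-accuracy points per block; mft_day_slope
    is theta power (μV²) per day; hemoglobin contrasts are mM.
    """

    online_rate_mean: dict[str, float] = None
    online_rate_sd: dict[str, float] = None
    variance_shrink_factor: dict[str, float] = None
    mft_day_slope: dict[str, float] = None
    dlpfc_hboxy_day4_minus_day1: dict[str, float] = None
    theta_base_power: float = 4.0          # μV² baseline oscillation power
    alpha_base_power: float = 4.0
    eeg_noise_sd: float = 0.5              # μV broadband pink-noise scale
    fnirs_od_noise_sd: float = 1e-4        # OD units
    flight_vspeed_noise_sd: float = 120.0  # ft/min at skill = 1
    flight_drift_noise_m: float = 25.0     # lateral drift at skill = 1
    nback_start_scaled: float = 24.0       # day-1 block-1 target scaled accuracy
    offline_gain_mean: float = 1.0         # scaled points between days
    offline_gain_sd: float = 0.5
    missed_landing_rate_day1: float = 0.10
    missed_landing_rate_day4: float = 0.02

    def __post_init__(self) -> None:
        self.online_rate_mean = _per_group(
            self.online_rate_mean, {g: 1.5 for g in GROUP_LABELS})
        self.online_rate_sd = _per_group(
            self.online_rate_sd, {g: 1.0 for g in GROUP_LABELS})
        self.variance_shrink_factor = _per_group(
            self.variance_shrink_factor,
            {"DLPFC_stim": 0.25, "DLPFC_sham": 1.0, "M1_stim": 1.0, "M1_sham": 1.0})
        self.mft_day_slope = _per_group(
            self.mft_day_slope,
            {"DLPFC_stim": 1.0, "DLPFC_sham": 0.0, "M1_stim": 0.0, "M1_sham": 0.0})
        self.dlpfc_hboxy_day4_minus_day1 = _per_group(
            self.dlpfc_hboxy_day4_minus_day1,
            {"DLPFC_stim": -0.0024, "DLPFC_sham": -0.0004,
             "M1_stim": -0.0011, "M1_sham": -0.0001})
        for g, f in self.variance_shrink_factor.items():
            if f <= 0:
                raise ConfigurationError("variance_shrink_factor must be > 0")
            if g not in STIM_GROUPS and f != 1.0 and g in ("DLPFC_sham", "M1_sham"):
                # permitted, but sham defaults to 1 (no shrink)
                pass
        for g, sd in self.online_rate_sd.items():
            if sd < 0:
                raise ConfigurationError("online_rate_sd must be ≥ 0")

    def rate_sd_for(self, group: str) -> float:
        """Between-subject SD of true online rates, shrink applied."""
        return self.online_rate_sd[group] * self.variance_shrink_factor[group] ** 0.5


def load_layout(path=None) -> pd.DataFrame:
    """Load a channel layout (columns label, x, y).

    With no path, returns the packaged neutral 31-channel 10-10 layout
    (schematic 2-D head projection; includes Fz and FC1).
    """
    if path is None:
        with resources.files("flightlearn.data").joinpath("layout31.csv").open() as f:
            return pd.read_csv(f)
    return pd.read_csv(path)
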