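"""EEG band-power extraction: 1-s Hann-tapered FFT epochs, theta/alpha bands.

Raw multichannel EEG (500 Hz) is high-pass filtered at 0.5 Hz, segmented per
task into sequential 1-s epochs, Hann windowed, and band power is the mean
FFT power over the band's integer frequencies (theta 4–7 Hz, alpha 8–12 Hz).
Epochs whose channel-average power exceeds mean + 2 SD are rejected; missing
subject cells are imputed with the group/day mean; midline-frontal theta
(MFT) is the mean theta power over Fz and FC1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError, DataError

BANDS = {"theta": (4, 7), "alpha": (8, 12)}


@dataclass
class EEGRecord:
    """Channel × time sample matrix (μV) with 10-10 channel labels and task
    segment annotations [(task, start_sample, stop_sample), ...]."""

    data: np.ndarray
    fs: float
    ch_names: list[str]
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise DataError("data must be (n_channels, n_samples) matching ch_names")


def highpass(record: EEGRecord, fc: float = 0.5, order: int = 2) -> EEGRecord:
    """Butterworth high-pass (order 2 = 12 dB/octave), applied zero-phase
    (forward-backward); band power is phase-insensitive and zero-phase
    filtering avoids group delay across epoch boundaries."""
    sos = signal.butter(order, fc, btype="highpass", fs=record.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, record.data, axis=-1)
    return EEGRecord(filtered, record.fs, list(record.ch_names), list(record.segments))


def epoch_and_power(data: np.ndarray, fs: float, band: tuple[int, int]) -> np.ndarray:
    """Per-epoch, per-channel mean band power (μV²).

    The segment is cut into non-overlapping 1-s epochs (fs samples, so bins
    fall on integer frequencies), Hann windowed, and the one-sided FFT power
    spectrum — window-power normalised so the bin sum equals the windowed
    signal variance (Parseval) — is averaged over the band's integer bins.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = int(round(fs))
    if data.shape[-1] < n:
        raise DataError("segment shorter than one 1-s epoch")
    lo, hi = band
    if hi >= fs / 2:
        raise ConfigurationError(f"band {band} exceeds Nyquist for fs={fs}")
    n_ep = data.shape[-1] // n
    epochs = data[:, : n_ep * n].reshape(data.shape[0], n_ep, n)
    w = signal.windows.hann(n, sym=False)
    xw = epochs * w
    spec = np.fft.rfft(xw, axis=-1)
    power = np.abs(spec) ** 2 / (n * np.sum(w ** 2))
    power[..., 1:-1] *= 2.0  # one-sided doubling (skip DC and Nyquist)
    bins = np.arange(lo, hi + 1)
    return power[..., bins].mean(axis=-1).T  # (n_epochs, n_channels)


def full_spectrum_power(x: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """One-sided power of a single 1-s epoch over all bins and the
    window-corrected time-domain variance (Parseval pair)."""
    n = int(round(fs))
    w = signal.windows.hann(n, sym=False)
    xw = np.asarray(x, dtype=float)[:n] * w
    spec = np.fft.rfft(xw)
    power = np.abs(spec) ** 2 / (n * np.sum(w ** 2))
    power[1:-1] *= 2.0
    return power, float(np.sum(xw ** 2) / np.sum(w ** 2))


def reject_epochs(powers_by_band: dict[str, np.ndarray], k: float = 2.0) -> np.ndarray:
    """Keep-mask over epochs: an epoch is rejected when its channel-average
    power in any band exceeds the across-epoch mean + k·SD (one-sided high:
    artifacts inflate power)."""
    masks = []
    for p in powers_by_band.values():
        avg = np.asarray(p).mean(axis=1)
        masks.append(avg <= avg.mean() + k * avg.std(ddof=1))
    return np.logical_and.reduce(masks)


def band_power_cell(data: np.ndarray, fs: float, k: float = 2.0) -> dict[str, np.ndarray]:
    """Epoch, reject, and average one task segment → per-channel mean power
    for each band (the subject/day/task cell of a BandPowerTable)."""
    powers = {b: epoch_and_power(data, fs, rng) for b, rng in BANDS.items()}
    keep = reject_epochs(powers, k=k)
    if not keep.any():
        keep = np.ones(len(keep), dtype=bool)
    return {b: p[keep].mean(axis=0) for b, p in powers.items()}


def band_power_table(cells: list[dict]) -> pd.DataFrame:
    """Assemble long-format table rows {subject, group, day, task, channel,
    band, power} from per-cell dicts."""
    return pd.DataFrame(cells)


def impute_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing power cells with the mean of the same
    (group, day, task, channel, band) cell across present subjects.

    Missing cells are rows with NaN power. An entirely missing group/day cell
    cannot be imputed and raises DataError.
    """
    out = table.copy()
    out["imputed"] = out["power"].isna()
    keys = [k for k in ("group", "day", "task", "channel", "band") if k in out.columns]
    means = out.groupby(keys)["power"].transform("mean")
    if out.loc[out["imputed"], "power"].size and means[out["imputed"]].isna().any():
        raise DataError("a group/day cell is entirely missing; cannot impute")
    out.loc[out["imputed"], "power"] = means[out["imputed"]]
    return out


def midline_frontal_theta(table: pd.DataFrame,
                          electrodes: tuple[str, str] = ("Fz", "FC1")) -> pd.DataFrame:
    """Per subject (and day/task where present): mean theta power across the
    two midline-frontal electrodes."""
    theta = table[(table["band"] == "theta") & (table["channel"].isin(electrodes))]
    if theta["channel"].nunique() < len(electrodes):
        raise DataError(f"table lacks electrodes {electrodes}")
    keys = [k for k in ("subject", "group", "day", "task") if k in table.columns]
    out = theta.groupby(keys, as_index=False)["power"].mean()
    return out.rename(columns={"power": "mft"})
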