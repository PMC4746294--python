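"""Readers and writers for the package's on-disk formats.

Telemetry is CSV (t_s, lat_deg, lon_deg, alt_ft_agl, vspeed_ftmin); n-back
events are JSON-lines (one trial per line); EEG is a raw float32 matrix with
a JSON sidecar (fs, channel labels, segments); fNIRS optical density is CSV
per wavelength with a channel-map JSON; ground truth is YAML.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eeg_spectral import EEGRecord
from .errors import DataError
from .flight_metrics import FlightTrace
from .fnirs import ChannelMap, OpticalDensityRecord
from .nback import NBackBlock, NBackLog

TELEMETRY_COLUMNS = ["t_s", "lat_deg", "lon_deg", "alt_ft_agl", "vspeed_ftmin"]


def write_telemetry(trace: FlightTrace, path) -> None:
    pd.DataFrame({
        "t_s": trace.t, "lat_deg": trace.lat, "lon_deg": trace.lon,
        "alt_ft_agl": trace.alt, "vspeed_ftmin": trace.vspeed,
    }).to_csv(path, index=False)


def read_telemetry(path) -> FlightTrace:
    df = pd.read_csv(path)
    missing = [c for c in TELEMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"telemetry CSV missing columns {missing}")
    return FlightTrace(t=df["t_s"].to_numpy(), lat=df["lat_deg"].to_numpy(),
                       lon=df["lon_deg"].to_numpy(), alt=df["alt_ft_agl"].to_numpy(),
                       vspeed=df["vspeed_ftmin"].to_numpy())


def write_nback_log(log: NBackLog, path) -> None:
    with open(path, "w") as f:
        for b in log.blocks:
            for i in range(b.n_trials):
                f.write(json.dumps({
                    "subject": log.subject, "day": b.day, "block": b.block_index,
                    "n_level": b.n_level, "trial": i + 1,
                    "position_correct": bool(b.position_correct[i]),
                    "image_correct": bool(b.image_correct[i]),
                }) + "\n")


def read_nback_log(path) -> NBackLog:
    rows = [json.loads(line) for line in open(path) if line.strip()]
    if not rows:
        raise DataError("empty n-back log")
    subject = rows[0]["subject"]
    blocks = []
    for (day, block, n_level), grp in pd.DataFrame(rows).groupby(
            ["day", "block", "n_level"], sort=True):
        grp = grp.sort_values("trial")
        blocks.append(NBackBlock(block_index=int(block), day=int(day),
                                 n_level=int(n_level),
                                 position_correct=grp["position_correct"].to_numpy(),
                                 image_correct=grp["image_correct"].to_numpy()))
    blocks.sort(key=lambda b: b.block_index)
    return NBackLog(subject=subject, blocks=blocks)


def write_eeg(record: EEGRecord, prefix) -> None:
    """Raw float32 channel-major matrix + JSON sidecar at prefix.{f32,json}."""
    prefix = Path(prefix)
    record.data.astype(np.float32).tofile(prefix.with_suffix(".f32"))
    sidecar = {"fs": record.fs, "ch_names": record.ch_names,
               "n_samples": record.data.shape[1],
               "segments": [list(s) for s in record.segments]}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg(prefix) -> EEGRecord:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".f32"), dtype=np.float32)
    data = data.reshape(len(sidecar["ch_names"]), sidecar["n_samples"]).astype(float)
    return EEGRecord(data=data, fs=sidecar["fs"], ch_names=sidecar["ch_names"],
                     segments=[tuple(s) for s in sidecar["segments"]])


def write_fnirs(record: OpticalDensityRecord, prefix) -> None:
    """One OD CSV per wavelength plus the channel-map JSON."""
    prefix = Path(prefix)
    for lam, od in record.od.items():
        pd.DataFrame(od, columns=record.channel_map.channels).to_csv(
            f"{prefix}_od{int(lam)}.csv", index=False)
    cmap = record.channel_map
    meta = {"fs": record.fs, "wavelengths": sorted(record.od),
            "channels": [{"channel": ch,
                          "source": ch.split("-")[0], "detector": ch.split("-")[-1],
                          "distance_cm": cmap.distance_cm[ch],
                          "roi": cmap.roi.get(ch)}
                         for ch in cmap.channels]}
    Path(f"{prefix}_channels.json").write_text(json.dumps(meta, indent=1))


def read_fnirs(prefix) -> OpticalDensityRecord:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}_channels.json").read_text())
    cmap = ChannelMap(
        channels=[c["channel"] for c in meta["channels"]],
        distance_cm={c["channel"]: c["distance_cm"] for c in meta["channels"]},
        roi={c["channel"]: c["roi"] for c in meta["channels"]},
    )
    od = {float(lam): pd.read_csv(f"{prefix}_od{int(lam)}.csv").to_numpy()
          for lam in meta["wavelengths"]}
    return OpticalDensityRecord(od=od, fs=meta["fs"], channel_map=cmap)


def write_ground_truth(ground_truth: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(ground_truth, sort_keys=False))


def read_ground_truth(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
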