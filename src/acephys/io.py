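"""Plain-text and raw-binary readers/writers for the pipeline's file formats.

Spike trains travel as two TSVs (events: unit_id, time_s; units: per-unit
metadata), trials as CSV with semicolon-separated lick times, LFP as raw
little-endian float32 channel-major binary plus a JSON sidecar, and ground
truth / results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BehaviorSession, LFPBlock, QualityMetrics, SpikeTrain

__all__ = [
    "write_spike_trains", "read_spike_trains",
    "write_trials", "read_trials",
    "write_lfp", "read_lfp",
    "write_json", "read_json",
]


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def write_spike_trains(trains: list[SpikeTrain], spikes_path, units_path) -> None:
    events = pd.DataFrame({
        "unit_id": np.concatenate([np.full(t.n_spikes, t.unit_id, dtype=int) for t in trains])
        if trains else np.array([], dtype=int),
        "time_s": np.concatenate([t.spike_times for t in trains])
        if trains else np.array([]),
    })
    events.to_csv(spikes_path, sep="\t", index=False)

    rows = []
    for t in trains:
        q = t.quality or QualityMetrics()
        rows.append({
            "unit_id": t.unit_id,
            "trough_to_peak_ms": t.trough_to_peak_ms,
            "max_channel": t.max_channel,
            "depth_um": t.depth_um,
            "region": t.region,
            "cell_type": t.cell_type,
            "layer": t.layer,
            "isolation_distance": q.isolation_distance,
            "overall_rate_hz": q.overall_rate_hz,
            "rp_contamination": q.rp_contamination,
            "noise_cutoff_sd": q.noise_cutoff_sd,
            "low_bin_fraction": q.low_bin_fraction,
        })
    pd.DataFrame(rows).to_csv(units_path, sep="\t", index=False)


def read_spike_trains(spikes_path, units_path) -> list[SpikeTrain]:
    events = pd.read_csv(spikes_path, sep="\t")
    meta = pd.read_csv(units_path, sep="\t")
    grouped = {uid: np.sort(g["time_s"].to_numpy(float)) for uid, g in events.groupby("unit_id")}

    def _val(row, key):
        v = row.get(key)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    trains = []
    for _, row in meta.iterrows():
        uid = int(row["unit_id"])
        quality = QualityMetrics(
            isolation_distance=_val(row, "isolation_distance"),
            overall_rate_hz=_val(row, "overall_rate_hz"),
            rp_contamination=_val(row, "rp_contamination"),
            noise_cutoff_sd=_val(row, "noise_cutoff_sd"),
            low_bin_fraction=_val(row, "low_bin_fraction"),
        )
        trains.append(SpikeTrain(
            unit_id=uid,
            spike_times=grouped.get(uid, np.array([])),
            trough_to_peak_ms=_val(row, "trough_to_peak_ms"),
            max_channel=None if _val(row, "max_channel") is None else int(row["max_channel"]),
            depth_um=_val(row, "depth_um"),
            region=str(row.get("region", "AC")),
            cell_type=_val(row, "cell_type"),
            layer=_val(row, "layer"),
            quality=quality,
        ))
    return trains


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def write_trials(session: BehaviorSession, path) -> None:
    df = session.trials.copy()
    df["intensity_db"] = [
        "catch" if c else f"{i:g}" for c, i in zip(df["is_catch"], df["intensity_db"])
    ]
    df["lick_times"] = [";".join(f"{x:.6f}" for x in licks) for licks in df["lick_times"]]
    df.insert(0, "trial_id", np.arange(len(df)))
    df.drop(columns=["is_catch"]).to_csv(path, index=False)


def read_trials(path, response_window_s: float = 1.0) -> BehaviorSession:
    df = pd.read_csv(path, dtype={"intensity_db": str}, keep_default_na=False)
    is_catch = df["intensity_db"].str.lower() == "catch"
    intensity = pd.to_numeric(df["intensity_db"], errors="coerce")
    licks = [
        np.array([float(x) for x in str(s).split(";") if x not in ("", "nan")])
        for s in df.get("lick_times", [""] * len(df))
    ]
    trials = pd.DataFrame({
        "onset_s": df["onset_s"].astype(float),
        "intensity_db": intensity,
        "is_catch": is_catch,
        "lick_times": licks,
    })
    return BehaviorSession(trials=trials, response_window_s=response_window_s)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def write_lfp(lfp: LFPBlock, bin_path, meta_path) -> None:
    lfp.data.astype("<f4").tofile(bin_path)
    meta = {
        "n_channels": lfp.n_channels,
        "n_samples": lfp.n_samples,
        "sampling_rate": lfp.sampling_rate,
        "channel_spacing_mm": lfp.channel_spacing_mm,
        "probe": lfp.probe,
        "channel_depths_um": None if lfp.channel_depths_um is None
        else np.asarray(lfp.channel_depths_um, float).tolist(),
        "dtype": "<f4",
        "order": "channel-major",
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_lfp(bin_path, meta_path) -> LFPBlock:
    meta = json.loads(Path(meta_path).read_text())
    data = np.fromfile(bin_path, dtype=meta.get("dtype", "<f4"))
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    depths = meta.get("channel_depths_um")
    return LFPBlock(
        data=data.astype(float),
        sampling_rate=float(meta["sampling_rate"]),
        channel_depths_um=None if depths is None else np.asarray(depths, float),
        channel_spacing_mm=float(meta.get("channel_spacing_mm", 0.05)),
        probe=meta.get("probe", "silicon"),
    )


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def read_json(path):
    return json.loads(Path(path).read_text())
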