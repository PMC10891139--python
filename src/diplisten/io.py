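"""Delimited-text and JSON interchange for spike trains, trial tables and traces.

Spike trains travel as long-format CSV (unit_id, trial_index, spike_time_s);
trial tables as the CSV written by :mod:`diplisten.behavior`; raw voltage
traces as binary float32 with a JSON sidecar carrying the sampling rate.
Every table carries a schema version; readers reject unknown versions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SpikeTrain

SCHEMA_VERSION = 1
_SCHEMA_COMMENT = f"# diplisten-schema: {SCHEMA_VERSION}\n"


def write_spike_table(trains: dict[int, list[SpikeTrain]] | list[SpikeTrain], path) -> None:
    if isinstance(trains, dict):
        flat = [st for per_unit in trains.values() for st in per_unit]
    else:
        flat = list(trains)
    rows = [
        (st.unit_id, st.trial_index, t)
        for st in flat
        for t in np.asarray(st.spike_times_s)
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "trial_index", "spike_time_s"])
    with open(path, "w") as fh:
        fh.write(_SCHEMA_COMMENT)
        df.to_csv(fh, index=False)


def read_spike_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# diplisten-schema:"):
            raise ValueError("missing schema header")
        version = int(header.split(":")[1])
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {version}")
        return pd.read_csv(fh)


def spike_table_to_trains(df: pd.DataFrame, trial_indices=None) -> dict[int, list[SpikeTrain]]:
    """Rebuild per-unit SpikeTrain lists; empty trials are preserved when the
    full trial index list is supplied."""
    out: dict[int, list[SpikeTrain]] = {}
    for uid, unit_df in df.groupby("unit_id"):
        trials = trial_indices if trial_indices is not None \
            else sorted(unit_df["trial_index"].unique())
        per_trial = {int(ti): g["spike_time_s"].to_numpy()
                     for ti, g in unit_df.groupby("trial_index")}
        out[int(uid)] = [
            SpikeTrain(int(uid), int(ti), np.sort(per_trial.get(int(ti), np.empty(0))))
            for ti in trials
        ]
    return out


def write_trace(trace: np.ndarray, fs: float, path_base) -> tuple[Path, Path]:
    """Binary float32 trace + JSON sidecar (sampling rate, length, channels)."""
    base = Path(path_base)
    raw = base.with_suffix(".f32")
    meta = base.with_suffix(".json")
    arr = np.asarray(trace, dtype=np.float32)
    arr.tofile(raw)
    meta.write_text(json.dumps({
        "schema_version": SCHEMA_VERSION,
        "sample_rate_hz": fs,
        "n_samples": int(arr.shape[-1]),
        "n_channels": int(arr.shape[0]) if arr.ndim == 2 else 1,
        "dtype": "float32",
    }, indent=2))
    return raw, meta


def read_trace(path_base) -> tuple[np.ndarray, float]:
    base = Path(path_base)
    meta = json.loads(base.with_suffix(".json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported trace schema version")
    arr = np.fromfile(base.with_suffix(".f32"), dtype=np.float32)
    if meta["n_channels"] > 1:
        arr = arr.reshape(meta["n_channels"], meta["n_samples"])
    return arr.astype(float), float(meta["sample_rate_hz"])
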