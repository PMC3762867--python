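"""Disk formats: trial-metadata CSV plus an HDF5 signal container.

The CSV holds one row per trial (trial_id, video_phoneme, audio_phoneme,
response, category, audio_onset).  The HDF5 file holds one dataset per
trial (``trial_<id>``) with ``fs`` and ``t0`` attributes, a ``/channels``
group with electrode metadata, and free-form provenance attributes on
the root.  Files are written with HDF5 object timestamps disabled so
identical runs produce identical bytes.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochArray, TrialRecord, trials_from_frame, trials_to_frame

TRIALS_CSV = "trials.csv"
EPOCHS_H5 = "epochs.h5"


def save_dataset(
    out_dir: str | Path,
    trials: list[TrialRecord],
    epochs: list[EpochArray],
    provenance: dict | None = None,
) -> Path:
    """Write trials.csv and epochs.h5 under ``out_dir``; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_to_frame(trials).to_csv(out / TRIALS_CSV, index=False)
    with h5py.File(out / EPOCHS_H5, "w", track_order=True) as f:
        for t, ep in zip(trials, epochs):
            d = f.create_dataset(
                f"trial_{t.trial_id:05d}", data=ep.data, track_times=False
            )
            d.attrs["fs"] = ep.fs
            d.attrs["t0"] = ep.t0
        info = epochs[0].channel_info
        if info is not None:
            g = f.create_group("channels")
            for col in info.columns:
                vals = info[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals, track_times=False)
        for key, val in (provenance or {}).items():
            f.attrs[key] = json.dumps(val) if isinstance(val, (dict, list)) else val
    return out


def load_dataset(in_dir: str | Path) -> tuple[list[TrialRecord], list[EpochArray]]:
    """Read back a (trials, epochs) pair written by :func:`save_dataset`."""
    ind = Path(in_dir)
    csv = ind / TRIALS_CSV
    h5 = ind / EPOCHS_H5
    for p in (csv, h5):
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
    trials = trials_from_frame(pd.read_csv(csv))
    epochs: list[EpochArray] = []
    with h5py.File(h5, "r") as f:
        info = None
        if "channels" in f:
            cols = {}
            for col in f["channels"]:
                vals = f["channels"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            info = pd.DataFrame(cols)
            info.index.name = "electrode"
        for t in trials:
            d = f[f"trial_{t.trial_id:05d}"]
            epochs.append(
                EpochArray(
                    data=d[()],
                    fs=float(d.attrs["fs"]),
                    t0=float(d.attrs["t0"]),
                    channel_info=info,
                )
            )
    return trials, epochs


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_default))
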