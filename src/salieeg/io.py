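"""Readers and writers for the pipeline's on-disk formats.

Recordings and epochs go to HDF5; events, schedules and result tables to
TSV; curves and envelopes to CSV; configs, ground truth and reports to
JSON/YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import Epochs, Recording


def write_recording(path: str | Path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.attrs["fs"] = rec.fs
        f.attrs["reference"] = rec.reference
        f.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
        g = f.create_group("groups")
        for name, members in rec.groups.items():
            g.create_dataset(name, data=np.array(members, dtype="S"))


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        labels = [s.decode() for s in f["labels"][()]]
        groups = {name: [s.decode() for s in ds[()]]
                  for name, ds in f["groups"].items()}
        return Recording(f["data"][()], float(f.attrs["fs"]), labels,
                         groups, str(f.attrs["reference"]))


def write_epochs(path: str | Path, epochs: Epochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.attrs["fs"] = epochs.fs
        f.attrs["window"] = epochs.window
        f.create_dataset("labels", data=np.array(epochs.labels, dtype="S"))
        g = f.create_group("groups")
        for name, members in epochs.groups.items():
            g.create_dataset(name, data=np.array(members, dtype="S"))
        f.create_dataset("meta_json",
                         data=epochs.meta.to_json(orient="table"))
    # metadata also as a sidecar TSV for quick inspection
    epochs.meta.to_csv(Path(path).with_suffix(".meta.tsv"), sep="\t",
                       index=False)


def read_epochs(path: str | Path) -> Epochs:
    with h5py.File(path, "r") as f:
        labels = [s.decode() for s in f["labels"][()]]
        groups = {name: [s.decode() for s in ds[()]]
                  for name, ds in f["groups"].items()}
        meta = pd.read_json(f["meta_json"][()].decode(), orient="table")
        return Epochs(f["data"][()], float(f.attrs["fs"]),
                      tuple(f.attrs["window"]), meta.reset_index(drop=True),
                      labels, groups)


def write_events_tsv(path: str | Path, events: pd.DataFrame) -> None:
    cols = ["time", "slope", "peak", "strength", "tier", "scene"]
    out = events[[c for c in cols if c in events.columns]].rename(
        columns={"time": "time_s"})
    out.insert(1, "kind", "salient")
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").rename(columns={"time_s": "time"})
    return df.drop(columns=[c for c in ("kind",) if c in df.columns])


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_curve_csv(path: str | Path, values: np.ndarray, fs: float) -> None:
    t = np.arange(len(values)) / fs
    pd.DataFrame({"time_s": t, "value": values}).to_csv(path, index=False)


def config_hash(d: dict) -> str:
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    return str(x)
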