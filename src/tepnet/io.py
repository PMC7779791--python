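"""File round-trips: HDF5 epoch container and delimited-text tables.

HDF5 layout: ``/epochs`` float dataset with shape (subject, condition,
electrode, epoch, time), ``/retained`` boolean mask over the first four
axes, and a root attribute ``meta`` holding a JSON string with subjects,
conditions, electrodes, the time axis and the sampling rate.

All text output uses a fixed ``%.17g`` float format: identical runs are
byte-identical and every double round-trips exactly, so staged CLI runs
reproduce the in-memory pipeline bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochSet

__all__ = [
    "write_epochs_h5", "read_epochs_h5",
    "write_table", "read_table",
    "write_labels", "read_labels",
    "write_json", "read_json",
]

FLOAT_FORMAT = "%.17g"


def write_epochs_h5(path, epochs: EpochSet) -> None:
    meta = {
        "subjects": list(epochs.subjects),
        "conditions": list(epochs.conditions),
        "electrodes": list(epochs.electrodes),
        "times_ms": epochs.times.tolist(),
        "sampling_rate": epochs.sampling_rate,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("retained", data=epochs.retained)
        f.attrs["meta"] = json.dumps(meta)


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        data = f["epochs"][()]
        retained = f["retained"][()].astype(bool)
    return EpochSet(data=data, retained=retained,
                    subjects=meta["subjects"],
                    conditions=tuple(meta["conditions"]),
                    electrodes=meta["electrodes"],
                    times=np.asarray(meta["times_ms"], dtype=float),
                    sampling_rate=meta["sampling_rate"])


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def write_labels(path, labels: pd.Series) -> None:
    df = labels.rename("group").to_frame()
    severity = labels.attrs.get("severity")
    if severity is not None:
        df["severity"] = [severity[s] for s in df.index]
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    labels = df["group"]
    if "severity" in df.columns:
        labels.attrs["severity"] = df["severity"].to_dict()
    return labels


def _round_floats(obj, ndigits: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_json(path, obj: dict) -> None:
    Path(path).write_text(
        json.dumps(_round_floats(obj), indent=1, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
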