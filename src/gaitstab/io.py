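"""CSV readers/writers for signals, events and feature tables.

Signal files are plain CSV with a single comment header line carrying the
sampling rate, e.g.::

    # fs=100.0
    t,ap,ml,vt
    0.00,0.12,-0.03,0.98
    ...

Feature tables are ordinary CSV with a header row; the reserved columns are
``subject_id`` (unique key), ``group`` (HC/PwS) and ``is_synthetic``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .types import GaitEvents, TriaxialSignal


def write_signal_csv(path: str | Path, signal: TriaxialSignal) -> None:
    path = Path(path)
    t = np.arange(signal.n_samples) / signal.fs
    df = pd.DataFrame({"t": t, "ap": signal.ap, "ml": signal.ml, "vt": signal.vt})
    with open(path, "w") as fh:
        fh.write(f"# fs={signal.fs}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_signal_csv(path: str | Path) -> TriaxialSignal:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise SchemaError(f"{path}: expected '# fs=<Hz>' header line, got {first!r}")
        try:
            fs = float(first.split("=", 1)[1])
        except ValueError as exc:
            raise SchemaError(f"{path}: unparseable sampling rate in {first!r}") from exc
        df = pd.read_csv(fh)
    missing = {"ap", "ml", "vt"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return TriaxialSignal(fs=fs, ap=df["ap"].to_numpy(), ml=df["ml"].to_numpy(),
                          vt=df["vt"].to_numpy())


def write_series_csv(path: str | Path, x: np.ndarray, fs: float, name: str = "x") -> None:
    t = np.arange(len(x)) / fs
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        pd.DataFrame({"t": t, name: x}).to_csv(fh, index=False, float_format="%.6g")


def read_series_csv(path: str | Path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise SchemaError(f"{path}: expected '# fs=<Hz>' header line")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    value_cols = [c for c in df.columns if c != "t"]
    if len(value_cols) != 1:
        raise SchemaError(f"{path}: expected exactly one value column, got {value_cols}")
    return df[value_cols[0]].to_numpy(), fs


def write_events_csv(path: str | Path, events: GaitEvents) -> None:
    rows = [("IC", int(i)) for i in events.ic_indices] + [
        ("TO", int(i)) for i in events.to_indices
    ]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["event_type", "sample_index"]).to_csv(path, index=False)


def read_events_csv(path: str | Path, fs: float) -> GaitEvents:
    df = pd.read_csv(path)
    if not {"event_type", "sample_index"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns event_type,sample_index")
    ic = df.loc[df.event_type == "IC", "sample_index"].to_numpy()
    to = df.loc[df.event_type == "TO", "sample_index"].to_numpy()
    return GaitEvents(ic_indices=np.sort(ic), to_indices=np.sort(to), fs=fs)


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" in df.columns and df["subject_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate subject_id values")
    return df


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
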