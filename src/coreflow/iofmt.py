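"""Readers/writers: raw event tables, underway metadata logs, bead tables, records.

Event files hold one row per detected particle with five optical channels
(two position detectors d1/d2, forward scatter, red and orange fluorescence)
and come either as headed CSV or as the self-describing little-endian
``binary-v1`` layout (magic ``CFB1``, uint32 version, uint32 row count,
float64 rows in column order d1,d2,fsc,red,orange).  Metadata files are
SFL-style underway logs, one row per three-minute acquisition file.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["d1", "d2", "fsc", "red", "orange"]

METADATA_COLUMNS = [
    "file_id", "cruise_id", "timestamp", "lat", "lon", "duration",
    "flow_rate", "flow_rate_se", "stream_pressure", "event_rate",
    "sst", "salinity", "par",
]

_ESD_SUFFIXES = ["n135", "n138", "n141"]

#: fixed, order-stable column set of the curated per-population record file
OUTPUT_COLUMNS = (
    ["cruise", "file_id", "time", "lat", "lon", "population", "n",
     "abundance", "abundance_se", "abundance_se_count",
     "fsc_med", "fsc_q25", "fsc_q75",
     "red_med", "red_q25", "red_q75",
     "orange_med", "orange_q25", "orange_q75"]
    + [f"esd_{s}_{sfx}" for sfx in _ESD_SUFFIXES for s in ("med", "q25", "q75")]
    + [f"carbon_{s}_{sfx}" for sfx in _ESD_SUFFIXES for s in ("med", "q25", "q75")]
    + ["flag_pressure", "flag_rate", "flag_abundance", "flag_esd", "flag_carbon",
       "sst", "salinity", "par"]
)

_MAGIC = b"CFB1"
_BINARY_VERSION = 1


class SchemaError(ValueError):
    """A required column is absent or the file layout is not recognized."""


class ValidationError(ValueError):
    """Values violate the event-table invariants (finite, non-negative)."""


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"event table is missing required column {col!r}")
    out = df.loc[:, EVENT_COLUMNS].apply(pd.to_numeric, errors="coerce")
    out = out.reset_index(drop=True)
    arr = out.to_numpy(dtype=np.float64)
    bad = ~np.isfinite(arr)
    if bad.any():
        i = int(np.argwhere(bad)[0][0])
        raise ValidationError(f"non-finite channel value at row {i}")
    neg = arr < 0
    if neg.any():
        i = int(np.argwhere(neg)[0][0])
        raise ValidationError(f"negative channel value at row {i}")
    return out


def read_events(path, dialect: str = "csv", file_id: str | None = None) -> pd.DataFrame:
    """Read one acquisition file into a validated event table.

    Returns a DataFrame with columns d1,d2,fsc,red,orange; the file id is
    carried in ``df.attrs['file_id']`` (defaults to the file stem).
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "binary-v1":
        raw = path.read_bytes()
        if raw[:4] != _MAGIC:
            raise SchemaError(f"{path}: bad magic bytes for binary-v1")
        version, nrows = struct.unpack_from("<II", raw, 4)
        if version != _BINARY_VERSION:
            raise SchemaError(f"{path}: unsupported binary version {version}")
        data = np.frombuffer(raw, dtype="<f8", count=nrows * 5, offset=12)
        df = pd.DataFrame(data.reshape(nrows, 5), columns=EVENT_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'binary-v1'")
    df = _validate_events(df)
    df.attrs["file_id"] = file_id if file_id is not None else path.stem
    return df


def write_events(events: pd.DataFrame, path, dialect: str = "csv") -> None:
    df = _validate_events(events)
    path = Path(path)
    if dialect == "csv":
        df.to_csv(path, index=False)
    elif dialect == "binary-v1":
        arr = np.ascontiguousarray(df.to_numpy(dtype="<f8"))
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<II", _BINARY_VERSION, len(df)))
            fh.write(arr.tobytes())
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'binary-v1'")


def read_metadata(path, default_se_fraction: float = 0.05) -> pd.DataFrame:
    """Read the per-file underway log; one row per acquisition file.

    Rows are returned sorted by timestamp (stable sort, with a warning if the
    file was out of order).  A missing flow_rate_se column or missing entries
    default to ``default_se_fraction * flow_rate``.  Missing environmental
    fields stay as nulls; they are never filled with zeros.
    """
    df = pd.read_csv(path)
    for col in METADATA_COLUMNS:
        if col not in df.columns and col != "flow_rate_se":
            raise SchemaError(f"metadata is missing required column {col!r}")
    if df["file_id"].duplicated().any():
        dups = sorted(df.loc[df["file_id"].duplicated(), "file_id"].unique())
        raise ValidationError(f"duplicate file_id(s) in metadata: {dups}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if "flow_rate_se" not in df.columns:
        df["flow_rate_se"] = np.nan
    df["flow_rate_se"] = df["flow_rate_se"].fillna(default_se_fraction * df["flow_rate"])
    for grp_id, grp in df.groupby("cruise_id"):
        if not grp["timestamp"].is_monotonic_increasing:
            warnings.warn(f"cruise {grp_id}: timestamps out of order; applying stable sort")
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return df.loc[:, METADATA_COLUMNS]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.loc[:, [c for c in METADATA_COLUMNS if c in meta.columns]].to_csv(path, index=False)


def read_bead_calibration(path) -> pd.DataFrame:
    """Bead calibration table: diameter (um), refractive_index, measured_norm_scatter."""
    df = pd.read_csv(path)
    for col in ("diameter", "refractive_index", "measured_norm_scatter"):
        if col not in df.columns:
            raise SchemaError(f"bead table is missing required column {col!r}")
    if (df["diameter"] <= 0).any():
        raise ValidationError("bead diameters must be positive")
    one = df.loc[np.isclose(df["diameter"], 1.0), "measured_norm_scatter"]
    if len(one) and not np.allclose(one, 1.0, rtol=1e-6):
        raise ValidationError("the 1-um bead row must have measured_norm_scatter == 1")
    return df


def write_bead_calibration(beads: pd.DataFrame, path) -> None:
    beads.to_csv(path, index=False)


def write_population_records(summaries: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Write the curated per-population CSV (one row per file x population).

    ``summaries`` must carry every OUTPUT_COLUMNS field except the
    metadata-derived ones (cruise, time, lat, lon, sst, salinity, par), which
    are joined in here from ``meta``.  Any summary file_id without metadata is
    an error.
    """
    meta = meta.set_index("file_id")
    missing = sorted(set(summaries["file_id"]) - set(meta.index))
    if missing:
        raise ValidationError(f"no metadata for file_id(s): {missing}")
    out = summaries.copy()
    join = meta.loc[out["file_id"]]
    out["cruise"] = join["cruise_id"].to_numpy()
    out["time"] = join["timestamp"].to_numpy()
    for col in ("lat", "lon", "sst", "salinity", "par"):
        out[col] = join[col].to_numpy()
    for col in OUTPUT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out.loc[:, OUTPUT_COLUMNS].to_csv(path, index=False)


def read_population_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OUTPUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"population record file is missing columns: {missing}")
    return df
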