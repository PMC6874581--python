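"""Per-file x per-population summary records.

Each curated record summarizes one population in one three-minute acquisition
file: particle count, abundance with its calibration SE (Poisson SE kept
separately), median/25%/75% of the bead-normalized optical channels, and
median/25%/75% ESD and carbon quota at each of the three cell refractive
indices.  Quantiles use linear interpolation between order statistics
(type-7), for bit-reproducibility.  Beads are emitted as a population row —
they are gated and normalized against — but are not biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .iofmt import OUTPUT_COLUMNS, ValidationError
from .quantify import VirtualCoreVolume, abundance

_Q = (50.0, 25.0, 75.0)
_QNAMES = ("med", "q25", "q75")


def _triple(values: np.ndarray) -> list[float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return [np.nan, np.nan, np.nan]
    return [float(np.percentile(v, q)) for q in _Q]


def summarize_file(labels: pd.Series, opp_norm: pd.DataFrame,
                   esd_tables: dict, carbon_tables: dict,
                   core: VirtualCoreVolume,
                   include_unknown: bool = True) -> pd.DataFrame:
    """Summary rows for one file.

    ``labels`` is the population assignment aligned row-wise with
    ``opp_norm`` (bead-normalized optical channels); ``esd_tables`` and
    ``carbon_tables`` map a refractive-index suffix ('n135', 'n138', 'n141')
    to per-particle arrays aligned the same way.  Populations absent from the
    file are omitted.
    """
    lab = np.asarray(labels, dtype=object)
    if len(lab) != len(opp_norm):
        raise ValueError("labels and OPP table must align row-wise")
    rows = []
    for pop in pd.unique(lab):
        if pop == "unknown" and not include_unknown:
            continue
        sel = lab == pop
        n = int(sel.sum())
        ab, se, se_n = abundance(n, core)
        row = {"file_id": core.file_id, "population": pop, "n": n,
               "abundance": ab, "abundance_se": se, "abundance_se_count": se_n}
        for ch in ("fsc", "red", "orange"):
            for name, val in zip(_QNAMES, _triple(opp_norm.loc[sel, ch].to_numpy(float))):
                row[f"{ch}_{name}"] = val
        for sfx in ("n135", "n138", "n141"):
            for name, val in zip(_QNAMES, _triple(np.asarray(esd_tables[sfx])[sel])):
                row[f"esd_{name}_{sfx}"] = val
            for name, val in zip(_QNAMES, _triple(np.asarray(carbon_tables[sfx])[sel])):
                row[f"carbon_{name}_{sfx}"] = val
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("population", kind="stable").reset_index(drop=True)
    return out


def merge_metadata(summaries: pd.DataFrame, meta: pd.DataFrame,
                   qc_flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Left-join ship metadata (and per-file QC flags) onto summary rows.

    Referential integrity is enforced: a summary whose file_id has no
    metadata raises.  Null metadata fields propagate as nulls.  The result
    has exactly one row per input summary row, with the fixed curated column
    set in stable order.
    """
    m = meta.set_index("file_id")
    orphans = sorted(set(summaries["file_id"]) - set(m.index))
    if orphans:
        raise ValidationError(f"summary rows reference unknown file_id(s): {orphans}")
    out = summaries.copy()
    join = m.loc[out["file_id"]]
    out["cruise"] = join["cruise_id"].to_numpy()
    out["time"] = join["timestamp"].to_numpy()
    for col in ("lat", "lon", "sst", "salinity", "par"):
        out[col] = join[col].to_numpy()
    if qc_flags is not None:
        f = qc_flags.set_index("file_id")
        for col in ("flag_pressure", "flag_rate"):
            out[col] = f.loc[out["file_id"], col].to_numpy()
    for col in OUTPUT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out.loc[:, OUTPUT_COLUMNS]
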