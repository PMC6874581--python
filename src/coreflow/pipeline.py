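"""End-to-end orchestration: raw events -> curated per-population records.

Stage order: bead identification and filtration fit (pooled over the cruise),
OPP selection per file, population classification, bead-normalized Mie
sizing and carbon quotas, abundance quantification, QC flagging, aggregation
and the metadata merge.  Identical inputs and seed reproduce identical
output bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from . import aggregate, iofmt, mie_sizing as mz, qc, quantify
from .classification import GatingSpec, classify
from .filtration import FiltrationParams, fit_filtration_params, opp_ratio, select_opp

ESD_SUFFIX = {1.35: "n135", 1.38: "n138", 1.41: "n141"}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and file id."""

    def __init__(self, stage: str, file_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on file {file_id!r}: {cause}")
        self.stage = stage
        self.file_id = file_id


@dataclass
class CruiseResult:
    records: pd.DataFrame
    filtration: FiltrationParams
    mie_model: mz.MieModel
    calibration_r2: float
    bead_medians: dict
    opp: dict          # file_id -> OPP table (raw channels)
    labels: dict       # file_id -> population Series
    run_log: dict


def bead_mask_from_spec(events: pd.DataFrame, spec: GatingSpec) -> np.ndarray:
    """Apply the beads polygon of a gating spec to a raw event table."""
    gate = spec.gates[0]
    if gate.population != "beads":
        raise ValueError("gating spec must start with the beads gate")
    ok = (events[list(gate.channels)] > 0).all(axis=1).to_numpy()
    pts = np.log10(events.loc[ok, list(gate.channels)].to_numpy(dtype=np.float64))
    mask = np.zeros(len(events), dtype=bool)
    mask[np.flatnonzero(ok)[MplPath(np.asarray(gate.polygon)).contains_points(pts)]] = True
    return mask


def process_cruise(events: dict, metadata: pd.DataFrame, bead_table: pd.DataFrame,
                   spec: GatingSpec, *, quantile: float = 50.0,
                   mie_model: mz.MieModel | None = None, calibrate: bool = True,
                   include_unknown: bool = True, seed: int = 0) -> CruiseResult:
    """Run the full processing chain on in-memory inputs.

    ``events`` maps file_id to a raw event table; every file_id must appear
    in ``metadata``.  Filtration parameters and bead normalization medians
    are fit once on beads pooled across the cruise, mirroring per-cruise
    instrument calibration.
    """
    if not events:
        raise ValueError("no event files")
    meta_ids = set(metadata["file_id"])
    missing = sorted(set(events) - meta_ids)
    if missing:
        raise ValueError(f"metadata missing for file_id(s): {missing}")

    # --- filtration fit on pooled beads -------------------------------------
    pooled = pd.concat(events.values(), ignore_index=True)
    bead_mask = bead_mask_from_spec(pooled, spec)
    try:
        params = fit_filtration_params(pooled, bead_mask)
    except Exception as e:  # noqa: BLE001 - reported with stage context
        raise StageError("filtration-fit", "<pooled>", e) from e

    # --- optical calibration ------------------------------------------------
    model = mie_model if mie_model is not None else mz.MieModel()
    r2 = float("nan")
    if calibrate:
        model, r2 = mz.calibrate_geometry(bead_table, model)
    lookups = {n: mz._cached_lookup(model, n) for n in model.n_cells}

    # --- per-file OPP selection ---------------------------------------------
    opp_tables, ratios = {}, {}
    for fid, ev in events.items():
        try:
            opp = select_opp(ev, params, quantile)
            opp_tables[fid] = opp
            ratios[fid] = opp_ratio(opp, ev)
        except Exception as e:  # noqa: BLE001
            raise StageError("filtration", fid, e) from e

    # --- cruise bead normalization medians (from gated OPP beads) -----------
    opp_all = pd.concat(opp_tables.values(), ignore_index=True)
    opp_bead_mask = bead_mask_from_spec(opp_all, spec)
    if not opp_bead_mask.any():
        raise StageError("normalization", "<pooled>",
                         ValueError("no OPP beads found for normalization"))
    bead_med = {ch: float(opp_all.loc[opp_bead_mask, ch].median())
                for ch in ("fsc", "red", "orange")}

    # --- classify, size, quantify, summarize --------------------------------
    labels_by_file, summaries = {}, []
    meta_by_id = metadata.set_index("file_id", drop=False)
    for fid, opp in opp_tables.items():
        try:
            labels = classify(opp, spec, seed=seed)
        except Exception as e:  # noqa: BLE001
            raise StageError("classification", fid, e) from e
        labels_by_file[fid] = labels
        try:
            norm = opp[["fsc", "red", "orange"]].div(pd.Series(bead_med))
            esd_tables, carbon_tables = {}, {}
            for n, sfx in ESD_SUFFIX.items():
                esd, _flags = lookups[n].esd(norm["fsc"].to_numpy())
                esd_tables[sfx] = esd
                carbon_tables[sfx] = mz.carbon_from_volume(mz.esd_to_volume(esd))
        except Exception as e:  # noqa: BLE001
            raise StageError("sizing", fid, e) from e
        try:
            core = quantify.virtual_core_volume(ratios[fid], meta_by_id.loc[fid])
            summaries.append(aggregate.summarize_file(
                labels, norm, esd_tables, carbon_tables, core,
                include_unknown=include_unknown))
        except Exception as e:  # noqa: BLE001
            raise StageError("quantification", fid, e) from e

    summary = pd.concat(summaries, ignore_index=True)

    # --- QC and final merge --------------------------------------------------
    inst_flags = qc.flag_instrument(metadata)
    chauv = qc.chauvenet_flags(summary, metadata)
    summary = pd.concat([summary, chauv], axis=1)
    records = aggregate.merge_metadata(summary, metadata, qc_flags=inst_flags)
    records = records.sort_values(["file_id", "population"],
                                  kind="stable").reset_index(drop=True)

    run_log = {
        "filtration_id": params.filtration_id,
        "gating_id": spec.gating_id,
        "quantile": quantile,
        "seed": seed,
        "n_files": len(events),
        "mie_geometry": {"inner_deg": model.inner_deg, "outer_deg": model.outer_deg},
        "mie_calibration_r2": r2,
        "bead_medians": bead_med,
        "alignment_tol": params.alignment_tol,
    }
    return CruiseResult(records=records, filtration=params, mie_model=model,
                        calibration_r2=r2, bead_medians=bead_med, opp=opp_tables,
                        labels=labels_by_file, run_log=run_log)


def run_pipeline(input_dir, out_dir, *, dialect: str = "csv",
                 quantile: float = 50.0, seed: int = 0,
                 include_unknown: bool = True) -> CruiseResult:
    """Filesystem front end: read a simulated/curated input directory, write outputs.

    Expects ``<input_dir>/events/`` with event files, plus metadata.csv,
    beads.csv and gating.json.  Writes curated.csv, filtration.json and
    run_log.json under ``out_dir``.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    event_dir = input_dir / "events"
    ext = "csv" if dialect == "csv" else "bin"
    paths = sorted(event_dir.glob(f"*.{ext}"))
    if not paths:
        raise ValueError(f"no event files under {event_dir}")
    events = {p.stem: iofmt.read_events(p, dialect=dialect) for p in paths}
    metadata = iofmt.read_metadata(input_dir / "metadata.csv")
    bead_table = iofmt.read_bead_calibration(input_dir / "beads.csv")
    spec = load_gating_spec(input_dir / "gating.json")

    result = process_cruise(events, metadata, bead_table, spec,
                            quantile=quantile, seed=seed,
                            include_unknown=include_unknown)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out_dir / "curated.csv", index=False)
    (out_dir / "filtration.json").write_text(json.dumps({
        "filtration_id": result.filtration.filtration_id,
        "bead_fsc": result.filtration.bead_fsc,
        "bead_d1": result.filtration.bead_d1,
        "bead_d2": result.filtration.bead_d2,
        "alignment_tol": result.filtration.alignment_tol,
        "slopes": {f"{d}/{s}/{q}": v for (d, s, q), v
                   in sorted(result.filtration.slopes.items())},
    }, indent=2, sort_keys=True))
    (out_dir / "run_log.json").write_text(
        json.dumps(result.run_log, indent=2, sort_keys=True))
    return result


def dump_gating_spec(spec: GatingSpec, path) -> None:
    payload = {
        "gates": [{"population": g.population, "channels": list(g.channels),
                   "polygon": [list(v) for v in g.polygon]} for g in spec.gates],
        "cluster_params": {
            "channels": list(spec.cluster_params.channels),
            "grid_size": spec.cluster_params.grid_size,
            "bandwidth": spec.cluster_params.bandwidth,
            "contour_mass": spec.cluster_params.contour_mass,
            "min_density": spec.cluster_params.min_density,
            "min_points": spec.cluster_params.min_points,
            "merge_saddle": spec.cluster_params.merge_saddle,
        },
        "picoeuk_thresholds": spec.picoeuk_thresholds,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_gating_spec(path) -> GatingSpec:
    from .classification import ClusterParams, Gate

    payload = json.loads(Path(path).read_text())
    gates = tuple(Gate(g["population"], tuple(g["channels"]),
                       tuple(tuple(v) for v in g["polygon"]))
                  for g in payload["gates"])
    cp = payload.get("cluster_params", {})
    cluster = ClusterParams(channels=tuple(cp.get("channels", ("fsc", "red"))),
                            grid_size=cp.get("grid_size", 128),
                            bandwidth=cp.get("bandwidth"),
                            contour_mass=cp.get("contour_mass", 1.0),
                            min_density=cp.get("min_density", 0.0),
                            min_points=cp.get("min_points", 30),
                            merge_saddle=cp.get("merge_saddle", 0.5))
    return GatingSpec(gates=gates, cluster_params=cluster,
                      picoeuk_thresholds=payload.get("picoeuk_thresholds", {}))


def write_simulation(result, out_dir, dialect: str = "csv") -> None:
    """Materialize a SimulationResult as a pipeline input directory."""
    out_dir = Path(out_dir)
    (out_dir / "events").mkdir(parents=True, exist_ok=True)
    ext = "csv" if dialect == "csv" else "bin"
    for fid, ev in result.events.items():
        iofmt.write_events(ev, out_dir / "events" / f"{fid}.{ext}", dialect=dialect)
    iofmt.write_metadata(result.metadata, out_dir / "metadata.csv")
    iofmt.write_bead_calibration(result.bead_table, out_dir / "beads.csv")
    dump_gating_spec(result.gating_spec, out_dir / "gating.json")
    result.truth.particles.to_csv(out_dir / "truth_particles.csv", index=False)
    result.truth.files.to_csv(out_dir / "truth_files.csv", index=False)
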