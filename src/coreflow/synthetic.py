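"""Ground-truthed cruise simulator.

Emits everything the pipeline consumes — per-file event tables, an underway
metadata log, a bead calibration table and a matched gating spec — from a
generative model with known population concentrations, so recovery can be
checked against truth.

Measurement model
-----------------
Particle arrivals in each three-minute file are Poisson with rate
(total concentration x flow).  Each particle draws a population, a lognormal
diameter, and two lateral coordinates in the stream: ``u`` along the
position-detector axis (the virtual core is |u| <= core_fraction) and ``v``,
a focal offset.  Forward scatter is the Mie detector response of the
particle's diameter and refractive index, attenuated by defocus
(exp(-defocus * |v|)) and multiplicative lognormal noise.  The position
detectors respond to the observed forward scatter through a (two-piece)
log-linear gain curve plus a position term: an even component
c * |u|^gain_power raising both detectors off-axis and an odd component
+/- s_a * u splitting them, so centred particles read equal and low,
off-axis particles read high and unequal.  Two modelling choices matter for
the statistics of the downstream boundary fit.  First, the even position
term is statistically independent of the forward-scatter defocus (separate
coordinates); coupling them through a single coordinate makes the OPP test
degenerate because the anchored regression absorbs any shared deterministic
position dependence.  Second, the defocus and position profiles are linear
in |v| and |u|, which for uniform lateral positions makes the residual
distributions around the gain curve symmetric; skewed profiles bias the
anchored quantile slopes and give the extrapolated boundary a
population-dependent acceptance.  Fluorescence is lognormal per population
and position-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from . import mie_sizing as mz
from .classification import ClusterParams, Gate, GatingSpec
from .iofmt import METADATA_COLUMNS

LN10 = np.log(10.0)

__all__ = ["PopulationSpec", "CoreModel", "SimulationConfig", "SimulationTruth",
           "simulate_cruise", "default_config"]


@dataclass(frozen=True)
class PopulationSpec:
    concentration: float      # cells per uL
    diameter_um: float        # lognormal median
    diameter_log_sd: float    # log10 units
    refractive_index: float
    red_log: float            # log10 fluorescence centre (arbitrary units)
    orange_log: float
    fluor_log_sd: float = 0.15


@dataclass(frozen=True)
class CoreModel:
    """Parametric virtual-core acceptance model (see module docstring)."""

    core_fraction: float = 0.25   # |u| below this is inside the core
    gain_even: float = 4.5        # c: even D1/D2 boost, ln units per |u|^gain_power
    gain_power: float = 1.0       # exponent of the even boost
    gain_odd: float = 0.5         # s_a: opposing lateral sensitivity, ln units per u
    defocus: float = 3.4          # forward-scatter attenuation, ln units per |v|
    slope_below: float = 1.0      # position-detector gain vs fsc, below anchor
    slope_above: float = 1.0
    gain_level: float = -0.5      # log10(d / fsc) at the anchor


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    cruise_id: str = "SIM001"
    n_files: int = 5
    duration: float = 180.0            # s
    flow_rate: float = 0.5             # mL/min
    flow_rate_se_fraction: float = 0.05
    populations: dict = field(default_factory=dict)
    bead_concentration: float = 1.5    # beads per uL
    bead_fluor_log_sd: float = 0.15
    core: CoreModel = CoreModel()
    noise_log_sd: float = 0.05         # per-channel multiplicative, log10
    fsc_scale_log: float = 4.7         # raw instrument units, log10
    fluor_scale_log: float = 3.0
    stream_pressure: float = 12.0      # psi
    pressure_fault_files: tuple = ()   # indices with injected pressure drift
    rate_burst_files: tuple = ()       # indices with injected event-rate bursts
    mie_model: mz.MieModel = mz.MieModel()
    start_time: str = "2017-06-01T00:00:00Z"
    lat0: float = 22.75
    lon0: float = -158.0


BEAD_SPEC = PopulationSpec(concentration=1.5, diameter_um=1.0, diameter_log_sd=0.0,
                           refractive_index=mz.BEAD_REFRACTIVE_INDEX,
                           red_log=-2.5, orange_log=0.0)

DEFAULT_POPULATIONS = {
    "prochloro": PopulationSpec(3.0, 0.55, 0.03, 1.38, red_log=-1.2, orange_log=-3.0),
    "synecho": PopulationSpec(0.8, 1.00, 0.03, 1.38, red_log=-1.0, orange_log=-1.0),
    "croco": PopulationSpec(0.06, 2.20, 0.03, 1.38, red_log=-2.2, orange_log=-1.0),
    "picoeuk": PopulationSpec(0.25, 1.70, 0.06, 1.38, red_log=0.3, orange_log=-3.0),
}

HARD_POPULATIONS = {
    # overlap mode: Prochlorococcus pushed toward the noise floor of the
    # scatter channel and closer to the picoeukaryotes in red fluorescence
    "prochloro": PopulationSpec(3.0, 0.45, 0.06, 1.35, red_log=-0.6, orange_log=-3.0),
    "synecho": PopulationSpec(0.8, 1.00, 0.05, 1.38, red_log=-0.9, orange_log=-1.0),
    "croco": PopulationSpec(0.06, 2.20, 0.05, 1.38, red_log=-2.2, orange_log=-1.0),
    "picoeuk": PopulationSpec(0.25, 1.30, 0.10, 1.41, red_log=0.1, orange_log=-3.0),
    "debris": PopulationSpec(0.5, 0.35, 0.15, 1.35, red_log=-3.5, orange_log=-3.5),
}


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(populations=dict(DEFAULT_POPULATIONS))
    return replace(cfg, **overrides) if overrides else cfg


def hard_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(populations=dict(HARD_POPULATIONS))
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimulationTruth:
    particles: pd.DataFrame   # file_id, population, diameter, u, v
    files: pd.DataFrame       # file_id, true core volume, per-pop concentration


@dataclass
class SimulationResult:
    events: dict              # file_id -> event DataFrame
    metadata: pd.DataFrame
    bead_table: pd.DataFrame
    gating_spec: GatingSpec
    truth: SimulationTruth
    config: SimulationConfig


@lru_cache(maxsize=32)
def _response_interp(model: mz.MieModel, n_particle: float):
    """(log10 diameter, log10 raw response) table for forward simulation."""
    grid = model.diameter_grid
    resp = mz.detector_response(grid, n_particle, model)
    return np.log10(grid), np.log10(resp)


def _intrinsic_log_scatter(diam, n_particle, model) -> np.ndarray:
    ld, lr = _response_interp(model, float(n_particle))
    return np.interp(np.log10(diam), ld, lr)


def _two_piece(x, anchor_x, anchor_y, s_lo, s_hi):
    x = np.asarray(x, dtype=np.float64)
    slope = np.where(x < anchor_x, s_lo, s_hi)
    return anchor_y + slope * (x - anchor_x)


def _design_anchors(cfg: SimulationConfig) -> tuple[float, float]:
    """(x, y) log10 anchor of the position-detector gain curve.

    Placed at the design median bead coordinate: intrinsic bead scatter 1,
    median defocus at median |v| = 1/2 for v ~ U(-1, 1).
    """
    ax = cfg.fsc_scale_log - cfg.core.defocus * 0.5 / LN10
    return ax, ax + cfg.core.gain_level


def simulate_cruise(config: SimulationConfig | None = None) -> SimulationResult:
    """Draw a full cruise: events, metadata, bead table, gating spec, truth."""
    cfg = config if config is not None else default_config()
    if not cfg.populations:
        raise ValueError("config.populations must not be empty")
    for name, p in cfg.populations.items():
        if p.concentration < 0:
            raise ValueError(f"population {name}: concentration must be >= 0")
        if p.diameter_log_sd < 0:
            raise ValueError(f"population {name}: diameter_log_sd must be >= 0")
    if not 0 < cfg.core.core_fraction < 1:
        raise ValueError("core_fraction must lie in (0, 1)")

    rng = np.random.default_rng(cfg.seed)
    model = cfg.mie_model
    names = list(cfg.populations) + ["beads"]
    specs = {**cfg.populations,
             "beads": replace(BEAD_SPEC, concentration=cfg.bead_concentration,
                              fluor_log_sd=cfg.bead_fluor_log_sd)}
    conc = np.array([specs[n].concentration for n in names])
    sample_ul = cfg.flow_rate * 1000.0 / 60.0 * cfg.duration
    ax, ay = _design_anchors(cfg)

    events = {}
    truth_rows = []
    meta_rows = []
    file_truth = []
    t0 = pd.Timestamp(cfg.start_time)
    for i in range(cfg.n_files):
        fid = f"{cfg.cruise_id}_f{i:04d}"
        n_ev = rng.poisson(conc.sum() * sample_ul)
        pop_idx = rng.choice(len(names), size=n_ev, p=conc / conc.sum())
        pop = np.array(names, dtype=object)[pop_idx]

        diam = np.empty(n_ev)
        n_idx = np.empty(n_ev)
        red = np.empty(n_ev)
        orange = np.empty(n_ev)
        for k, name in enumerate(names):
            sel = pop_idx == k
            s = specs[name]
            d = 10.0 ** (np.log10(s.diameter_um)
                         + s.diameter_log_sd * rng.standard_normal(sel.sum()))
            diam[sel] = np.clip(d, model.grid_min_um, model.grid_max_um)
            n_idx[sel] = s.refractive_index
            red[sel] = s.red_log + s.fluor_log_sd * rng.standard_normal(sel.sum())
            orange[sel] = s.orange_log + s.fluor_log_sd * rng.standard_normal(sel.sum())

        u = rng.uniform(-1.0, 1.0, n_ev)
        v = rng.uniform(-1.0, 1.0, n_ev)

        log_r = np.empty(n_ev)
        for n_p in np.unique(n_idx):
            sel = n_idx == n_p
            log_r[sel] = _intrinsic_log_scatter(diam[sel], n_p, model)

        sd = cfg.noise_log_sd
        log_fsc = (log_r + cfg.fsc_scale_log - cfg.core.defocus * np.abs(v) / LN10
                   + sd * rng.standard_normal(n_ev))
        base = _two_piece(log_fsc, ax, ay, cfg.core.slope_below, cfg.core.slope_above)
        even = cfg.core.gain_even * np.abs(u) ** cfg.core.gain_power / LN10
        odd = cfg.core.gain_odd * u / LN10
        log_d1 = base + even + odd + sd * rng.standard_normal(n_ev)
        log_d2 = base + even - odd + sd * rng.standard_normal(n_ev)

        df = pd.DataFrame({
            "d1": 10.0 ** log_d1,
            "d2": 10.0 ** log_d2,
            "fsc": 10.0 ** log_fsc,
            "red": 10.0 ** (red + cfg.fluor_scale_log),
            "orange": 10.0 ** (orange + cfg.fluor_scale_log),
        })
        df.attrs["file_id"] = fid
        events[fid] = df
        truth_rows.append(pd.DataFrame({
            "file_id": fid, "population": pop, "diameter": diam, "u": u, "v": v}))

        rate = 25000.0 if i in cfg.rate_burst_files else n_ev / cfg.duration
        pressure = cfg.stream_pressure * (1.10 if i in cfg.pressure_fault_files else 1.0)
        ts = t0 + pd.Timedelta(seconds=i * cfg.duration)
        meta_rows.append({
            "file_id": fid, "cruise_id": cfg.cruise_id, "timestamp": ts,
            "lat": cfg.lat0 + 0.005 * i, "lon": cfg.lon0 + 0.005 * i,
            "duration": cfg.duration, "flow_rate": cfg.flow_rate,
            "flow_rate_se": cfg.flow_rate_se_fraction * cfg.flow_rate,
            "stream_pressure": pressure, "event_rate": rate,
            "sst": 26.5 + 0.02 * np.sin(i / 5.0), "salinity": 35.2,
            "par": max(0.0, 1500.0 * np.sin(2 * np.pi * (i * cfg.duration / 86400.0 - 0.25))),
        })
        ft = {"file_id": fid, "sample_volume": sample_ul,
              "true_core_volume": cfg.core.core_fraction * sample_ul}
        for name in names:
            ft[f"conc_{name}"] = specs[name].concentration
        file_truth.append(ft)

    metadata = pd.DataFrame(meta_rows).loc[:, METADATA_COLUMNS]

    bead_d = np.array([0.3, 0.5, 0.75, 1.0, 1.83, 3.1, 5.7])
    bead_table = pd.DataFrame({
        "diameter": bead_d,
        "refractive_index": mz.BEAD_REFRACTIVE_INDEX,
        "measured_norm_scatter": mz.detector_response(bead_d,
                                                      mz.BEAD_REFRACTIVE_INDEX, model),
    })

    truth = SimulationTruth(particles=pd.concat(truth_rows, ignore_index=True),
                            files=pd.DataFrame(file_truth))
    return SimulationResult(events=events, metadata=metadata, bead_table=bead_table,
                            gating_spec=make_gating_spec(cfg), truth=truth,
                            config=cfg)


def make_gating_spec(cfg: SimulationConfig) -> GatingSpec:
    """Gate geometry matched to the configured populations, in raw log10 units.

    Boxes are +/-0.55 decades (3.7 sigma at the default fluorescence spread)
    around each population centre in its distinguishing channels, elongated
    downward along forward scatter to cover the defocus tail.
    """
    model = cfg.mie_model
    smear = cfg.core.defocus / LN10  # max downward defocus shift, decades
    half = 0.55

    def fsc_centre(spec: PopulationSpec) -> float:
        r = float(_intrinsic_log_scatter(np.array([spec.diameter_um]),
                                         spec.refractive_index, model)[0])
        return r + cfg.fsc_scale_log

    def box(cx_lo, cx_hi, cy_lo, cy_hi):
        return ((cx_lo, cy_lo), (cx_hi, cy_lo), (cx_hi, cy_hi), (cx_lo, cy_hi))

    fl = cfg.fluor_scale_log
    gates = []
    bead_fsc = cfg.fsc_scale_log  # intrinsic bead response is 1 by definition
    gates.append(Gate("beads", ("fsc", "orange"),
                      box(bead_fsc - smear - half, bead_fsc + half,
                          BEAD_SPEC.orange_log + fl - half,
                          BEAD_SPEC.orange_log + fl + half)))
    if "synecho" in cfg.populations:
        s = cfg.populations["synecho"]
        gates.append(Gate("synecho", ("orange", "red"),
                          box(s.orange_log + fl - half, s.orange_log + fl + half,
                              s.red_log + fl - half, s.red_log + fl + half)))
    if "croco" in cfg.populations:
        s = cfg.populations["croco"]
        c = fsc_centre(s)
        gates.append(Gate("croco", ("fsc", "orange"),
                          box(c - smear - half, c + half,
                              s.orange_log + fl - half, s.orange_log + fl + half)))

    thresholds = {}
    if "picoeuk" in cfg.populations:
        s = cfg.populations["picoeuk"]
        thresholds = {"red": s.red_log + fl - 0.75,
                      "fsc": fsc_centre(s) - smear - 0.45}
    return GatingSpec(gates=tuple(gates), cluster_params=ClusterParams(),
                      picoeuk_thresholds=thresholds)
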