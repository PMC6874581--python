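"""Assign OPP to phytoplankton populations.

Sequential strategy mirroring shipboard practice: manual polygon gates first
for the optically distinctive groups (calibration beads, then
phycoerythrin-rich *Synechococcus* and small *Crocosphaera*), then a
density-mode step for *Prochlorococcus* (the dominant low-scatter
red-fluorescing mode in (fsc, red) log space), then simple thresholds for
picoeukaryotes (high scatter, high red fluorescence).  Whatever remains is
labelled ``unknown``; every OPP receives exactly one label.

Polygons are given as vertex lists in log10 channel space.  Point-in-polygon
tests use matplotlib's path machinery; polygon validity (simple, >= 3
vertices) is checked with shapely when a spec is constructed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, ClassifierMixin

POPULATIONS = ("beads", "synecho", "croco", "prochloro", "picoeuk", "unknown")

#: fixed order of the manual gating sequence
GATE_ORDER = ("beads", "synecho", "croco")

__all__ = [
    "Gate", "ClusterParams", "GatingSpec", "PopulationGater",
    "apply_manual_gates", "cluster_prochloro", "label_picoeuk", "classify",
    "POPULATIONS",
]


@dataclass(frozen=True)
class Gate:
    population: str
    channels: tuple  # e.g. ("fsc", "orange")
    polygon: tuple   # ((x, y), ...) vertices in log10 space

    def __post_init__(self):
        if len(self.polygon) < 3:
            raise ValueError(f"gate {self.population}: polygon needs >= 3 vertices")
        poly = ShapelyPolygon(self.polygon)
        if not poly.is_valid:
            raise ValueError(f"gate {self.population}: polygon is self-intersecting")


@dataclass(frozen=True)
class ClusterParams:
    """Density-mode step: grid KDE on log10 channels, watershed basins."""

    channels: tuple = ("fsc", "red")
    grid_size: int = 128
    bandwidth: float | None = None  # log10 units; None = Silverman per axis
    contour_mass: float = 1.0       # fraction of basin mass kept (1 = whole basin)
    min_density: float = 0.0
    min_points: int = 30
    merge_saddle: float = 0.5       # merge basins whose saddle/peak ratio exceeds this


@dataclass(frozen=True)
class GatingSpec:
    """Ordered manual gates + cluster parameters + picoeukaryote thresholds.

    ``picoeuk_thresholds`` maps channel name to a minimum log10 value; a pool
    particle above every threshold is a picoeukaryote.
    """

    gates: tuple
    cluster_params: ClusterParams = ClusterParams()
    picoeuk_thresholds: dict = field(default_factory=dict)
    gating_id: str = field(default="", compare=False)

    def __post_init__(self):
        order = [g.population for g in self.gates]
        expected = [p for p in GATE_ORDER if p in order]
        if order != expected:
            raise ValueError(f"manual gates must follow order {GATE_ORDER}, got {order}")
        if not self.gating_id:
            payload = json.dumps(
                [[g.population, list(g.channels), [list(v) for v in g.polygon]]
                 for g in self.gates]
                + [sorted(self.picoeuk_thresholds.items())]
                + [[self.cluster_params.grid_size, self.cluster_params.bandwidth,
                    self.cluster_params.contour_mass, self.cluster_params.min_density]],
                sort_keys=True)
            object.__setattr__(
                self, "gating_id",
                hashlib.sha1(payload.encode()).hexdigest()[:12])


def _log10_channels(df: pd.DataFrame, channels) -> tuple[np.ndarray, np.ndarray]:
    ok = (df[list(channels)] > 0).all(axis=1).to_numpy()
    pts = np.full((len(df), 2), np.nan)
    sub = df.loc[ok, list(channels)].to_numpy(dtype=np.float64)
    pts[ok] = np.log10(sub)
    return pts, ok


def apply_manual_gates(opp: pd.DataFrame, spec: GatingSpec) -> pd.Series:
    """Sequential polygon gating; first containing gate wins.

    Returns a string Series aligned with ``opp`` where ungated particles hold
    the empty string.
    """
    labels = pd.Series("", index=opp.index, dtype=object)
    unassigned = np.ones(len(opp), dtype=bool)
    for gate in spec.gates:
        pts, ok = _log10_channels(opp, gate.channels)
        cand = unassigned & ok
        if not cand.any():
            continue
        inside = MplPath(np.asarray(gate.polygon)).contains_points(pts[cand])
        idx = np.flatnonzero(cand)[inside]
        labels.iloc[idx] = gate.population
        unassigned[idx] = False
    return labels


def _merge_shallow_saddles(basins: np.ndarray, dens: np.ndarray,
                           peaks: np.ndarray, saddle_ratio: float) -> np.ndarray:
    """Union watershed basins separated by a shallow valley.

    Sampling noise breaks an elongated density ridge into several local
    maxima; a real mode boundary is a deep valley.  Two adjacent basins are
    merged when the density at their shared boundary exceeds ``saddle_ratio``
    times the lower of their peak densities.  Scale-free, hence insensitive
    to the absolute cell count.
    """
    if saddle_ratio >= 1.0 or len(peaks) < 2:
        return basins
    peak_h = {i + 1: dens[r, c] for i, (r, c) in enumerate(peaks)}
    labels = {b: b for b in peak_h}

    def find(b):
        while labels[b] != b:
            labels[b] = labels[labels[b]]
            b = labels[b]
        return b

    # saddle height between adjacent basins: max over boundary pixel pairs of
    # the lower of the two densities
    saddle: dict = {}
    for axis in (0, 1):
        a = basins[:-1, :] if axis == 0 else basins[:, :-1]
        b = basins[1:, :] if axis == 0 else basins[:, 1:]
        da = dens[:-1, :] if axis == 0 else dens[:, :-1]
        db = dens[1:, :] if axis == 0 else dens[:, 1:]
        edge = a != b
        lo = np.minimum(da, db)[edge]
        for (ba, bb, h) in zip(a[edge].ravel(), b[edge].ravel(), lo.ravel()):
            ba, bb = int(ba), int(bb)
            key = (min(ba, bb), max(ba, bb))
            if h > saddle.get(key, -np.inf):
                saddle[key] = h
    merged = True
    while merged:
        merged = False
        for (ba, bb), h in saddle.items():
            ra, rb = find(ba), find(bb)
            if ra == rb:
                continue
            if h >= saddle_ratio * min(peak_h[ra], peak_h[rb]):
                root, child = (ra, rb) if peak_h[ra] >= peak_h[rb] else (rb, ra)
                labels[child] = root
                merged = True
    out = basins.copy()
    for b in list(peak_h):
        out[basins == b] = find(b)
    return out


def cluster_prochloro(pool: pd.DataFrame, params: ClusterParams = ClusterParams(),
                      seed: int = 0) -> pd.Series:
    """Label the dominant low-scatter red-fluorescing density mode.

    Builds a binned kernel density estimate of the pool in log10
    (fsc, red) space, splits it into watershed basins around its local
    maxima, and labels the particles of the most populated basin (ties break
    toward the lower-scatter basin).  Deterministic: the grid KDE and
    watershed involve no random draws; ``seed`` is accepted for interface
    stability.

    Returns a boolean Series (True = prochloro) aligned with ``pool``.
    """
    out = pd.Series(False, index=pool.index)
    if len(pool) < params.min_points:
        return out
    pts, ok = _log10_channels(pool, params.channels)
    xy = pts[ok]
    if len(xy) < params.min_points:
        return out

    g = params.grid_size
    if params.bandwidth is None:
        # Silverman per axis for a 2-D KDE
        n = len(xy)
        bw = xy.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)
        bw = np.maximum(bw, 1e-3)
    else:
        bw = np.array([params.bandwidth, params.bandwidth])
    lo = xy.min(axis=0) - 3 * bw
    hi = xy.max(axis=0) + 3 * bw
    hist, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=g,
                                  range=[[lo[0], hi[0]], [lo[1], hi[1]]])
    binw = (hi - lo) / g
    dens = gaussian_filter(hist, sigma=bw / binw)

    peaks = peak_local_max(dens, min_distance=max(2, g // 32),
                           threshold_rel=0.02, exclude_border=False)
    if len(peaks) == 0:
        return out
    markers = np.zeros_like(dens, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    basins = watershed(-dens, markers=markers)
    basins = _merge_shallow_saddles(basins, dens, peaks, params.merge_saddle)

    ix = np.clip(np.searchsorted(xe, xy[:, 0], side="right") - 1, 0, g - 1)
    iy = np.clip(np.searchsorted(ye, xy[:, 1], side="right") - 1, 0, g - 1)
    basin_of_point = basins[ix, iy]

    counts = np.bincount(basin_of_point, minlength=basins.max() + 1)
    best = counts[1:].max()
    cand = [b for b in range(1, len(counts)) if counts[b] >= 0.99 * best]
    if len(cand) > 1:  # tie: prefer the lower forward-scatter mode
        cand.sort(key=lambda b: xy[basin_of_point == b, 0].mean())
    chosen = cand[0]

    member = basin_of_point == chosen
    if params.min_density > 0 or params.contour_mass < 1.0:
        d_at = dens[ix, iy]
        keep = d_at >= params.min_density
        if params.contour_mass < 1.0:
            cut = np.quantile(d_at[member], 1.0 - params.contour_mass)
            keep &= d_at >= cut
        member &= keep
    out.iloc[np.flatnonzero(ok)[member]] = True
    return out


def label_picoeuk(pool: pd.DataFrame, thresholds: dict) -> pd.Series:
    """High-scatter, high-red particles -> picoeuk; the rest -> unknown."""
    labels = pd.Series("unknown", index=pool.index, dtype=object)
    if not len(pool):
        return labels
    mask = np.ones(len(pool), dtype=bool)
    for ch, thr in thresholds.items():
        v = pool[ch].to_numpy(dtype=np.float64)
        with np.errstate(divide="ignore"):
            lv = np.where(v > 0, np.log10(np.where(v > 0, v, 1.0)), -np.inf)
        mask &= lv > thr
    labels.iloc[np.flatnonzero(mask)] = "picoeuk"
    return labels


def classify(opp: pd.DataFrame, spec: GatingSpec, seed: int = 0) -> pd.Series:
    """Full five-step assignment; exactly one label per OPP row."""
    labels = apply_manual_gates(opp, spec)
    pool = opp.loc[labels == ""]
    pro = cluster_prochloro(pool, spec.cluster_params, seed=seed)
    labels.loc[pro.index[pro]] = "prochloro"
    rest = pool.loc[~pro]
    labels.loc[rest.index] = label_picoeuk(rest, spec.picoeuk_thresholds)
    return labels


class PopulationGater(BaseEstimator, ClassifierMixin):
    """Estimator wrapper for the sequential gating strategy.

    The gate geometry is supplied, not learned, so ``fit`` only validates the
    spec and records the class labels; ``predict(X)`` returns one population
    label per OPP row.
    """

    def __init__(self, spec: GatingSpec = None, seed: int = 0):
        self.spec = spec
        self.seed = seed

    def fit(self, X=None, y=None):
        if self.spec is None:
            raise ValueError("PopulationGater requires a GatingSpec")
        self.classes_ = np.array(POPULATIONS)
        self.gating_id_ = self.spec.gating_id
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "classes_")
        return classify(X, self.spec, seed=self.seed).to_numpy()
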