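"""Virtual-core filtration: find optimally-positioned particles (OPP).

The instrument has no sheath flow; instead, two position-sensitive detectors
(d1, d2) locate each particle laterally in the sample stream.  Particles that
(i) scatter equally on both position detectors (aligned) and (ii) scatter
more in the forward direction than the position detectors predict (in focus)
lie inside the *virtual core*, where optical properties are measured
accurately.  The in-focus boundary is a pair of two-piece lines in log10
space — position-detector signal against forward scatter — anchored exactly
at the median 1-um bead coordinates, with per-segment slopes fit by anchored
quantile regression (pinball loss) at the 2.5/50/97.5% levels.  The 2.5%
boundary is the strictest, so OPP(2.5) is a subset of OPP(50) is a subset of
OPP(97.5).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

QUANTILES = (2.5, 50.0, 97.5)

__all__ = [
    "FiltrationParams",
    "VirtualCoreFilter",
    "fit_filtration_params",
    "select_opp",
    "opp_ratio",
    "anchored_quantile_slope",
]


def anchored_quantile_slope(x, y, x0: float, y0: float, tau: float) -> float:
    """Slope of the line through (x0, y0) minimizing the pinball loss at level tau.

    For points all on one side of the anchor the minimizer is a weighted
    quantile of the point slopes (y - y0)/(x - x0) with weights |x - x0|, at
    level tau for points right of the anchor and 1 - tau left of it.  Ties in
    the loss break toward the smaller slope.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = x - x0
    keep = w != 0
    w, y = w[keep], y[keep]
    if w.size == 0:
        raise ValueError("no points with x != x0 in segment")
    if not (np.all(w > 0) or np.all(w < 0)):
        raise ValueError("segment must lie entirely on one side of the anchor")
    level = tau if w[0] > 0 else 1.0 - tau
    slopes = (y - y0) / w
    weights = np.abs(w)
    order = np.argsort(slopes, kind="stable")
    slopes, weights = slopes[order], weights[order]
    cum = np.cumsum(weights)
    target = level * cum[-1]
    k = int(np.searchsorted(cum, target, side="left"))
    return float(slopes[min(k, slopes.size - 1)])


@dataclass(frozen=True)
class FiltrationParams:
    """Fitted OPP boundary: bead anchor, per-detector two-piece quantile slopes.

    ``slopes[(detector, segment, quantile)]`` with detector in {'d1','d2'},
    segment in {'below','above'} (relative to the anchor forward scatter) and
    quantile in QUANTILES.  Anchors are log10 channel values; the boundary for
    a quantile q and detector j is y = anchor_j + slope * (x - bead_fsc).
    Both segments meet at the anchor by construction.
    """

    bead_fsc: float
    bead_d1: float
    bead_d2: float
    slopes: dict
    alignment_tol: float
    quantiles: tuple = QUANTILES
    filtration_id: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.filtration_id:
            h = hashlib.sha1()
            h.update(np.array([self.bead_fsc, self.bead_d1, self.bead_d2,
                               self.alignment_tol]).round(12).tobytes())
            for key in sorted(self.slopes):
                h.update(repr((key, round(self.slopes[key], 12))).encode())
            object.__setattr__(self, "filtration_id", h.hexdigest()[:12])

    def boundary(self, detector: str, quantile: float, log_fsc):
        """Boundary line value(s) at log10 forward scatter ``log_fsc``."""
        if quantile not in self.quantiles:
            raise ValueError(f"unknown quantile {quantile}; have {self.quantiles}")
        x = np.asarray(log_fsc, dtype=np.float64)
        anchor = self.bead_d1 if detector == "d1" else self.bead_d2
        lo = self.slopes[(detector, "below", quantile)]
        hi = self.slopes[(detector, "above", quantile)]
        slope = np.where(x < self.bead_fsc, lo, hi)
        return anchor + slope * (x - self.bead_fsc)


def fit_filtration_params(events: pd.DataFrame, bead_mask,
                          quantiles=QUANTILES) -> FiltrationParams:
    """Fit the OPP boundary from bead-flagged rows of an event table.

    The anchor is the median log10 bead coordinate per channel; slopes come
    from anchored quantile regression of each position detector on forward
    scatter, separately below and above the anchor.  The alignment tolerance
    is the 97.5th percentile of |log10(d1/d2)| over the beads.
    """
    bead_mask = np.asarray(bead_mask, dtype=bool)
    beads = events.loc[bead_mask]
    if len(beads) < 50:
        raise ValueError(f"need >= 50 bead rows to fit filtration, got {len(beads)}")
    for col in ("d1", "d2", "fsc"):
        if (beads[col] <= 0).any():
            raise ValueError(f"bead rows must have strictly positive {col}")
    lx = np.log10(beads["fsc"].to_numpy())
    ld = {"d1": np.log10(beads["d1"].to_numpy()),
          "d2": np.log10(beads["d2"].to_numpy())}
    if lx.std() < 1e-9 or ld["d1"].std() < 1e-9 or ld["d2"].std() < 1e-9:
        raise ValueError("degenerate bead cloud: zero variance in a channel")

    x0 = float(np.median(lx))
    anchors = {det: float(np.median(v)) for det, v in ld.items()}
    quantiles = tuple(sorted(float(q) for q in quantiles))

    slopes: dict = {}
    for det in ("d1", "d2"):
        for seg, mask in (("below", lx < x0), ("above", lx > x0)):
            fitted = [anchored_quantile_slope(lx[mask], ld[det][mask], x0,
                                              anchors[det], q / 100.0)
                      for q in quantiles]
            # boundary ordering invariant: higher quantile lies higher at every
            # x, i.e. slopes non-decreasing in q above the anchor and
            # non-increasing below
            fitted = np.array(fitted)
            if seg == "above":
                fitted = np.maximum.accumulate(fitted)
            else:
                fitted = np.minimum.accumulate(fitted)
            for q, s in zip(quantiles, fitted):
                slopes[(det, seg, q)] = float(s)

    tol = float(np.percentile(np.abs(ld["d1"] - ld["d2"]), 97.5))
    return FiltrationParams(bead_fsc=x0, bead_d1=anchors["d1"],
                            bead_d2=anchors["d2"], slopes=slopes,
                            alignment_tol=tol, quantiles=quantiles)


def select_opp(events: pd.DataFrame, params: FiltrationParams,
               quantile: float) -> pd.DataFrame:
    """Rows of ``events`` inside the virtual core at the given quantile.

    A particle is OPP iff |log10 d1 - log10 d2| <= alignment_tol and both
    position-detector signals lie at or below their boundary lines at the
    particle's forward scatter.  Rows with a non-positive channel are dropped
    before the log transform.  The returned frame keeps the original index
    and adds an ``opp_quantile`` column with the tightest accepting quantile.
    """
    quantile = float(quantile)
    if quantile not in params.quantiles:
        raise ValueError(f"unknown quantile {quantile}; have {params.quantiles}")
    pos = (events[["d1", "d2", "fsc"]] > 0).all(axis=1).to_numpy()
    sub = events.loc[pos]
    lx = np.log10(sub["fsc"].to_numpy())
    l1 = np.log10(sub["d1"].to_numpy())
    l2 = np.log10(sub["d2"].to_numpy())
    aligned = np.abs(l1 - l2) <= params.alignment_tol

    def in_focus(q):
        return ((l1 <= params.boundary("d1", q, lx))
                & (l2 <= params.boundary("d2", q, lx)))

    accept = aligned & in_focus(quantile)
    out = sub.loc[accept].copy()
    # tightest quantile that accepts each retained particle
    tight = np.full(len(out), np.nan)
    sel_lx = lx[accept]
    sel_l1, sel_l2 = l1[accept], l2[accept]
    for q in sorted(params.quantiles, reverse=True):
        ok = ((sel_l1 <= params.boundary("d1", q, sel_lx))
              & (sel_l2 <= params.boundary("d2", q, sel_lx)))
        tight[ok] = q
    out["opp_quantile"] = tight
    out.attrs = dict(events.attrs)
    return out


def opp_ratio(opp: pd.DataFrame, events: pd.DataFrame) -> float:
    """Fraction of detected particles accepted as OPP."""
    if len(events) == 0:
        raise ValueError("event table is empty")
    return len(opp) / len(events)


class VirtualCoreFilter(BaseEstimator):
    """Estimator wrapper around the OPP boundary fit.

    fit(X, bead_mask=...) learns the anchored two-piece quantile boundary from
    the bead-flagged rows of an event table; transform(X) (or select(X, q))
    returns the OPP subset at ``quantile``.
    """

    def __init__(self, quantile: float = 50.0, quantiles=QUANTILES):
        self.quantile = quantile
        self.quantiles = quantiles

    def fit(self, X, y=None, *, bead_mask=None):
        if bead_mask is None:
            raise ValueError("fit requires bead_mask identifying calibration beads")
        self.params_ = fit_filtration_params(X, bead_mask, self.quantiles)
        return self

    def select(self, X, quantile=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        return select_opp(X, self.params_, self.quantile if quantile is None else quantile)

    def transform(self, X):
        return self.select(X)
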