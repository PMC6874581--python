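"""File-level instrument QC and Chauvenet outlier screening.

Instrument checks: a file fails if its stream pressure deviates by more than
5% from the cruise mean, or if the event rate exceeds 18,000 particles per
second (both strict inequalities).  Derived quantities (abundance, median
ESD, median carbon quota) are screened per cruise and population with the
classical single-pass Chauvenet criterion: flag x when
N * P(|Z| >= |x - mean| / sd) < 1/2 under the standard normal.  Flags are
tri-state — 'pass', 'fail', or 'na' where the input is null or the group is
too small to evaluate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, OutlierMixin

PRESSURE_TOL = 0.05
RATE_MAX = 18000.0

CHAUVENET_VARIABLES = {
    "flag_abundance": "abundance",
    "flag_esd": "esd_med_n138",
    "flag_carbon": "carbon_med_n138",
}

__all__ = ["flag_instrument", "chauvenet", "chauvenet_flags",
           "ChauvenetOutlierDetector", "PRESSURE_TOL", "RATE_MAX"]


def flag_instrument(meta: pd.DataFrame, pressure_tol: float = PRESSURE_TOL,
                    rate_max: float = RATE_MAX) -> pd.DataFrame:
    """Per-file pressure and event-rate flags ('pass'/'fail'/'na').

    The pressure reference is the mean over the file's cruise, computed from
    non-null pressures only; with every pressure null the flag is 'na'.
    """
    out = pd.DataFrame(index=meta.index)
    out["file_id"] = meta["file_id"]
    pressure = pd.to_numeric(meta["stream_pressure"], errors="coerce")
    rate = pd.to_numeric(meta["event_rate"], errors="coerce")

    flag_p = np.full(len(meta), "na", dtype=object)
    for _, grp in meta.groupby("cruise_id"):
        p = pressure.loc[grp.index]
        mean = p.mean()
        if not np.isfinite(mean) or mean == 0:
            continue
        dev = (p - mean).abs() / abs(mean)
        ok = dev.notna()
        flag_p[meta.index.get_indexer(grp.index[ok])] = np.where(
            dev[ok] > pressure_tol, "fail", "pass")
    out["flag_pressure"] = flag_p
    out["flag_rate"] = np.where(rate.isna(), "na",
                                np.where(rate > rate_max, "fail", "pass"))
    return out


def chauvenet(values) -> np.ndarray:
    """Boolean outlier mask by the single-pass Chauvenet criterion.

    Location-scale free: affine transforms of the series leave the mask
    unchanged.  A degenerate series (sd == 0) has no outliers; fewer than
    4 points is an error.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        raise ValueError("Chauvenet criterion needs at least 4 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("Chauvenet criterion requires finite values")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros(v.shape, dtype=bool)
    z = np.abs(v - v.mean()) / sd
    return v.size * 2.0 * norm.sf(z) < 0.5


def chauvenet_flags(summaries: pd.DataFrame, meta: pd.DataFrame,
                    variables: dict = CHAUVENET_VARIABLES) -> pd.DataFrame:
    """Chauvenet screen of derived quantities, per cruise and population.

    Bead rows are instrument calibration material, not biology, and are left
    'na'.  Groups with fewer than 4 finite values are 'na' as well.
    """
    cruise_of = meta.set_index("file_id")["cruise_id"]
    out = pd.DataFrame(index=summaries.index)
    cruise = summaries["file_id"].map(cruise_of)
    for flag_col, var in variables.items():
        flags = np.full(len(summaries), "na", dtype=object)
        if var in summaries.columns:
            vals = pd.to_numeric(summaries[var], errors="coerce")
            for (_, pop), grp in summaries.groupby([cruise, summaries["population"]]):
                if pop == "beads":
                    continue
                v = vals.loc[grp.index]
                ok = v.notna()
                if ok.sum() < 4:
                    continue
                mask = chauvenet(v[ok].to_numpy())
                loc = summaries.index.get_indexer(grp.index[ok])
                flags[loc] = np.where(mask, "fail", "pass")
        out[flag_col] = flags
    return out


class ChauvenetOutlierDetector(BaseEstimator, OutlierMixin):
    """sklearn-style wrapper: fit stores mean/sd, predict returns +1/-1.

    Follows the outlier-detector convention (-1 = outlier).  The criterion
    depends on the sample size seen at fit time.
    """

    def fit(self, X, y=None):
        v = np.asarray(X, dtype=np.float64).ravel()
        if v.size < 4:
            raise ValueError("Chauvenet criterion needs at least 4 values")
        self.mean_ = v.mean()
        self.sd_ = v.std(ddof=1)
        self.n_ = v.size
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mean_")
        v = np.asarray(X, dtype=np.float64).ravel()
        if self.sd_ == 0:
            return np.ones(v.shape, dtype=int)
        z = np.abs(v - self.mean_) / self.sd_
        return np.where(self.n_ * 2.0 * norm.sf(z) < 0.5, -1, 1)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)
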