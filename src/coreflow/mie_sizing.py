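"""Mie forward model of the forward-scatter detector and its inversion to cell size.

The instrument reports forward scatter normalized to 1-um calibration beads
(refractive index 1.60).  For a homogeneous sphere of diameter ``d`` and
refractive index ``n`` suspended in seawater (n_medium = 1.34), the light
collected by the forward detector is modeled as the unpolarized Mie phase
function integrated over an annular acceptance cone with two free half-angles.
Dividing by the same quantity for the bead gives the dimensionless
bead-normalized response.  Inverting a monotonized lookup of that response
yields the equivalent spherical diameter (ESD); carbon per cell follows the
empirical power law Qc = 0.261 * V^0.860 (fgC, V in um^3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "MieModel",
    "CarbonParams",
    "MonotoneLookup",
    "MieSizer",
    "mie_scattering",
    "detector_response",
    "calibrate_geometry",
    "build_lookup",
    "scatter_to_esd",
    "carbon_from_volume",
]

CELL_REFRACTIVE_INDICES = (1.35, 1.38, 1.41)
BEAD_REFRACTIVE_INDEX = 1.60


def _mie_coefficients(m: float, x: float) -> tuple[np.ndarray, np.ndarray]:
    """Mie series coefficients a_n, b_n for relative index m and size parameter x.

    Series truncated at N = ceil(x + 4 x^(1/3) + 2); the logarithmic
    derivative D_n(mx) is obtained by downward recurrence, the Riccati-Bessel
    functions psi_n, chi_n by upward recurrence.
    """
    if x <= 0:
        raise ValueError("size parameter x must be > 0")
    if m <= 0:
        raise ValueError("relative refractive index m must be > 0")
    nmax = int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x
    nstart = max(nmax, int(math.ceil(abs(mx)))) + 16
    D = np.zeros(nstart + 1, dtype=np.complex128)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    D = D[1 : nmax + 1]

    n = np.arange(1, nmax + 1, dtype=np.float64)
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_prev, psi[0] = math.cos(x), math.sin(x)   # psi_{-1}, psi_0
    chi_prev, chi[0] = -math.sin(x), math.cos(x)  # chi_{-1}, chi_0
    for k in range(1, nmax + 1):
        psi[k] = (2 * k - 1) / x * psi[k - 1] - psi_prev
        chi[k] = (2 * k - 1) / x * chi[k - 1] - chi_prev
        psi_prev, chi_prev = psi[k - 1], chi[k - 1]
    xi = psi - 1j * chi

    da = D / m + n / x
    db = D * m + n / x
    a = (da * psi[1:] - psi[:-1]) / (da * xi[1:] - xi[:-1])
    b = (db * psi[1:] - psi[:-1]) / (db * xi[1:] - xi[:-1])
    return a, b


def _amplitudes(a: np.ndarray, b: np.ndarray, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scattering amplitudes S1(mu), S2(mu) from the coefficient series."""
    mu = np.atleast_1d(np.asarray(mu, dtype=np.float64))
    nmax = a.size
    s1 = np.zeros(mu.shape, dtype=np.complex128)
    s2 = np.zeros(mu.shape, dtype=np.complex128)
    pi_prev = np.zeros_like(mu)   # pi_0
    pi_cur = np.ones_like(mu)     # pi_1
    for k in range(1, nmax + 1):
        tau = k * mu * pi_cur - (k + 1) * pi_prev
        f = (2 * k + 1) / (k * (k + 1))
        s1 += f * (a[k - 1] * pi_cur + b[k - 1] * tau)
        s2 += f * (a[k - 1] * tau + b[k - 1] * pi_cur)
        pi_next = ((2 * k + 1) * mu * pi_cur - (k + 1) * pi_prev) / k
        pi_prev, pi_cur = pi_cur, pi_next
    return s1, s2


def mie_scattering(m: float, x: float):
    """Scattering efficiency and unpolarized phase intensity for a sphere.

    Returns ``(qsca, phase)`` where ``phase(theta)`` evaluates
    (|S1|^2 + |S2|^2)/2 at scattering angle ``theta`` (radians).
    """
    a, b = _mie_coefficients(m, x)
    n = np.arange(1, a.size + 1, dtype=np.float64)
    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))

    def phase(theta):
        mu = np.cos(np.asarray(theta, dtype=np.float64))
        s1, s2 = _amplitudes(a, b, mu)
        out = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
        return out if out.size > 1 else float(out[0])

    return float(qsca), phase


def _annulus_power(m: float, x: float, inner_deg: float, outer_deg: float,
                   quad_order: int = 96) -> float:
    """Unnormalized power scattered into the annular cone [inner, outer] degrees.

    Gauss-Legendre quadrature of (|S1|^2 + |S2|^2)/2 * sin(theta); the common
    1/k^2 r^2 factor cancels in bead normalization and is omitted.
    """
    t1, t2 = math.radians(inner_deg), math.radians(outer_deg)
    nodes, wts = np.polynomial.legendre.leggauss(quad_order)
    theta = 0.5 * (t2 - t1) * nodes + 0.5 * (t2 + t1)
    a, b = _mie_coefficients(m, x)
    s1, s2 = _amplitudes(a, b, np.cos(theta))
    intens = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    return float(0.5 * (t2 - t1) * np.sum(wts * intens * np.sin(theta)))


@dataclass(frozen=True)
class CarbonParams:
    """Coefficients of the biovolume-to-carbon power law Qc = a * V^b."""

    a: float = 0.261
    b: float = 0.860

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("coefficient a must be > 0")
        if not 0 < self.b <= 1:
            raise ValueError("exponent b must lie in (0, 1]")


@dataclass(frozen=True)
class MieModel:
    """Optical model: laser, media, and forward-detector acceptance geometry.

    The acceptance annulus half-angles (degrees) are the only free geometry
    parameters; they are fit to a bead calibration table.  Defaults give a
    detector response that rises monotonically over the working size range.
    """

    wavelength_nm: float = 457.0
    n_medium: float = 1.34
    n_cells: tuple[float, ...] = CELL_REFRACTIVE_INDICES
    n_bead: float = BEAD_REFRACTIVE_INDEX
    inner_deg: float = 3.0
    outer_deg: float = 45.0
    grid_min_um: float = 0.2
    grid_max_um: float = 6.0
    grid_points: int = 2000
    quad_order: int = 96

    def __post_init__(self):
        if not 0.0 < self.inner_deg < self.outer_deg < 90.0:
            raise ValueError("acceptance annulus requires 0 < inner < outer < 90 degrees")

    @property
    def diameter_grid(self) -> np.ndarray:
        return np.geomspace(self.grid_min_um, self.grid_max_um, self.grid_points)

    def size_parameter(self, diameter_um) -> np.ndarray:
        """x = pi d n_medium / lambda, with the wavelength in the medium sense."""
        lam_um = self.wavelength_nm / 1000.0
        return np.pi * np.asarray(diameter_um, dtype=np.float64) * self.n_medium / lam_um

    def _bead_power(self) -> float:
        x = float(self.size_parameter(1.0))
        return _annulus_power(self.n_bead / self.n_medium, x,
                              self.inner_deg, self.outer_deg, self.quad_order)


def detector_response(diameter_um, n_particle: float, model: MieModel):
    """Bead-normalized forward-detector response of a homogeneous sphere.

    Equals 1.0 exactly for a 1-um sphere at the bead index (the normalization
    anchor).  ``diameter_um`` may be scalar or array; values outside the model
    grid range raise.
    """
    d = np.atleast_1d(np.asarray(diameter_um, dtype=np.float64))
    if np.any(d < model.grid_min_um) or np.any(d > model.grid_max_um):
        raise ValueError(
            f"diameter outside model grid range [{model.grid_min_um}, {model.grid_max_um}] um"
        )
    m = n_particle / model.n_medium
    bead = model._bead_power()
    x = model.size_parameter(d)
    out = np.array([_annulus_power(m, xi, model.inner_deg, model.outer_deg,
                                   model.quad_order) for xi in x])
    out /= bead
    return out if np.ndim(diameter_um) else float(out[0])


def calibrate_geometry(beads, model: MieModel) -> tuple[MieModel, float]:
    """Fit the acceptance half-angles to a bead calibration table.

    ``beads`` is a DataFrame with columns diameter, refractive_index,
    measured_norm_scatter.  Minimizes the sum of squared log10 residuals
    between predicted and measured normalized scatter; returns the updated
    model and the R^2 of the fit in log10 space.
    """
    d = np.asarray(beads["diameter"], dtype=np.float64)
    n_idx = np.asarray(beads["refractive_index"], dtype=np.float64)
    meas = np.asarray(beads["measured_norm_scatter"], dtype=np.float64)
    if d.size < 3:
        raise ValueError("bead calibration requires at least 3 bead rows")
    if np.log10(d.max() / d.min()) < 1.0:
        raise ValueError("bead diameters must span at least one decade")
    if np.any(d <= 0) or np.any(meas <= 0):
        raise ValueError("bead diameters and measured scatter must be positive")

    log_meas = np.log10(meas)

    def residuals(inner, outer):
        trial = replace(model, inner_deg=inner, outer_deg=outer)
        bead_pow = trial._bead_power()
        pred = np.array([
            _annulus_power(ni / trial.n_medium, float(trial.size_parameter(di)),
                           inner, outer, trial.quad_order) / bead_pow
            for di, ni in zip(d, n_idx)
        ])
        return np.log10(pred) - log_meas

    def loss(p):
        inner = math.exp(p[0])
        outer = inner + math.exp(p[1])
        if outer >= 89.9:
            return 1e6
        return float(np.sum(residuals(inner, outer) ** 2))

    p0 = np.array([math.log(model.inner_deg), math.log(model.outer_deg - model.inner_deg)])
    loss0 = loss(p0)
    res = minimize(loss, p0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
    if res.fun < loss0:
        best_inner = math.exp(res.x[0])
        best_outer = best_inner + math.exp(res.x[1])
        sse = float(res.fun)
    else:
        if res.fun > loss0 + 1e-15:
            warnings.warn("geometry optimization failed to improve; keeping initial angles")
        best_inner, best_outer = model.inner_deg, model.outer_deg
        sse = loss0
    sst = float(np.sum((log_meas - log_meas.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return replace(model, inner_deg=best_inner, outer_deg=best_outer), r2


@dataclass
class MonotoneLookup:
    """Single-valued diameter <-> normalized-scatter map on the model grid.

    Raw Mie response curves oscillate; the least-squares monotone
    (non-decreasing) envelope in log-log space makes the inversion
    single-valued.  Interpolation is linear in (log scatter, log diameter).
    """

    n_particle: float
    log_diameter: np.ndarray
    log_response: np.ndarray  # isotonic, non-decreasing

    def response(self, diameter_um):
        out = 10.0 ** np.interp(np.log10(diameter_um), self.log_diameter, self.log_response)
        return out if np.ndim(diameter_um) else float(out)

    def esd(self, norm_scatter):
        """Invert scatter to diameter; returns (esd_um, flag).

        flag: 0 in range, -1 clamped low / non-positive, +1 clamped high.
        ties on isotonic plateaus resolve toward the smaller diameter
        (np.interp takes the first grid value at a repeated abscissa).
        """
        s = np.atleast_1d(np.asarray(norm_scatter, dtype=np.float64))
        flag = np.zeros(s.shape, dtype=np.int8)
        esd = np.full(s.shape, np.nan)
        ok = np.isfinite(s) & (s > 0)
        flag[~ok] = -1
        ls = np.log10(s[ok])
        lo, hi = self.log_response[0], self.log_response[-1]
        f = np.zeros(ls.shape, dtype=np.int8)
        f[ls < lo] = -1
        f[ls > hi] = 1
        flag[ok] = f
        esd[ok] = 10.0 ** np.interp(ls, self.log_response, self.log_diameter)
        if np.ndim(norm_scatter):
            return esd, flag
        return float(esd[0]), int(flag[0])


def build_lookup(model: MieModel, n_particle: float) -> MonotoneLookup:
    """Evaluate the detector response over the grid and monotonize it."""
    grid = model.diameter_grid
    resp = detector_response(grid, n_particle, model)
    log_resp = np.log10(resp)
    iso = IsotonicRegression(increasing=True)
    mono = iso.fit_transform(np.arange(grid.size), log_resp)
    return MonotoneLookup(n_particle=n_particle,
                          log_diameter=np.log10(grid),
                          log_response=mono)


@lru_cache(maxsize=32)
def _cached_lookup(model: MieModel, n_particle: float) -> MonotoneLookup:
    """Memoized build_lookup; MieModel is frozen, hence hashable."""
    return build_lookup(model, n_particle)


def scatter_to_esd(norm_scatter, lookup: MonotoneLookup):
    """ESD (um) from bead-normalized scatter via the monotone lookup."""
    return lookup.esd(norm_scatter)


def carbon_from_volume(volume_um3, params: CarbonParams = CarbonParams()):
    """Carbon quota (fgC per cell) from cell volume via Qc = a * V^b."""
    v = np.asarray(volume_um3, dtype=np.float64)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    out = params.a * v**params.b
    return out if np.ndim(volume_um3) else float(out)


def esd_to_volume(esd_um):
    """Sphere volume (um^3) from diameter: V = pi/6 d^3."""
    d = np.asarray(esd_um, dtype=np.float64)
    return np.pi / 6.0 * d**3


class MieSizer(BaseEstimator, TransformerMixin):
    """Estimator wrapper: calibrate the optical geometry on beads, then size cells.

    fit(X) expects a bead calibration table (columns diameter,
    refractive_index, measured_norm_scatter); transform(X) maps an array of
    bead-normalized forward-scatter values to ESD at each cell refractive
    index, returning an (n, k) array ordered like ``n_cells``.
    """

    def __init__(self, wavelength_nm=457.0, n_medium=1.34,
                 n_cells=CELL_REFRACTIVE_INDICES, n_bead=BEAD_REFRACTIVE_INDEX,
                 inner_deg=3.0, outer_deg=45.0, calibrate=True):
        self.wavelength_nm = wavelength_nm
        self.n_medium = n_medium
        self.n_cells = n_cells
        self.n_bead = n_bead
        self.inner_deg = inner_deg
        self.outer_deg = outer_deg
        self.calibrate = calibrate

    def fit(self, X, y=None):
        model = MieModel(wavelength_nm=self.wavelength_nm, n_medium=self.n_medium,
                         n_cells=tuple(self.n_cells), n_bead=self.n_bead,
                         inner_deg=self.inner_deg, outer_deg=self.outer_deg)
        if self.calibrate and X is not None:
            model, r2 = calibrate_geometry(X, model)
            self.calibration_r2_ = r2
        else:
            self.calibration_r2_ = float("nan")
        self.model_ = model
        self.lookups_ = {n: build_lookup(model, n) for n in self.n_cells}
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        s = np.asarray(X, dtype=np.float64).ravel()
        cols = [self.lookups_[n].esd(s)[0] for n in self.n_cells]
        return np.column_stack(cols)
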