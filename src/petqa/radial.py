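"""Radial curve-fit detectability metrics.

A sub-resolution lesion takes the shape of the system point spread function,
so voxel values sampled around a candidate lesion center should decrease in
an organized way with radius.  The ROI sample is transformed into polar
coordinates about the maximum voxel (or the ROI center, for a manually
placed ROI) and two least-squares models are fitted:

* a third-order polynomial F(r) = F0 + F1 r + F2 r^2 + F3 r^3 over unsigned
  radii, solved in one linear step; coefficient standard deviations come from
  the residual-scaled inverse normal matrix;
* a four-parameter Gaussian G(r) = G0 exp(-((r - G1)/G2)^2) + G3 over signed
  radii (positive right of center, negative left), fitted iteratively by a
  gradient-expansion (Levenberg-Marquardt) scheme with at most 20 iterations
  and a chi-square change tolerance of 1e-3.  A fit that fails to converge
  zeroes every downstream metric — non-convergence on flat noise is itself
  evidence of an absent signal.

Derived metrics: polynomial-fit contrast (F0 - F(r_max))/(F0 + F(r_max)),
polynomial-fit SNR, raw contrast (max - min)/(max + min), Gaussian-fit
contrast/SNR/integral, and goodness-of-fit summaries (SEE, chi-square, max
coefficient-error ratio).

Note on the SNR definitions: the Gaussian amplitude G0 measures the peak
*above* the fitted background G3, and the Gaussian-fit SNR is (G0/σ(G0))².
The polynomial analog exposed by default is the fitted amplitude above the
far-field value, ((F0 - F(r_max))/σ(F0))², which reproduces the reference
background/lesion SNR magnitudes; the plain intercept form (F0/σ(F0))² is
available as ``snr_mode="intercept"``.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass, field

import numpy as np

from .localize import ROISample

logger = logging.getLogger("petqa")

__all__ = [
    "RadialProfile",
    "PolynomialFit",
    "GaussianFit",
    "FitQuality",
    "to_radial",
    "fit_polynomial",
    "poly_metrics",
    "raw_contrast",
    "fit_gaussian",
    "gauss_metrics",
    "fit_quality",
]


@dataclass
class RadialProfile:
    """(radius, value) pairs; radii in pixel units, optionally signed."""

    r: np.ndarray
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.r) != len(self.values):
            raise ValueError("radii and values must align")

    @property
    def r_max(self) -> float:
        return float(np.abs(self.r).max()) if len(self.r) else 0.0


@dataclass
class PolynomialFit:
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros(4))  # F0..F3
    sigma: np.ndarray = field(default_factory=lambda: np.zeros(4))  # sigma(F_N)
    see: float = 0.0
    chi2: float = 0.0
    converged: bool = False

    @property
    def F0(self) -> float:
        return float(self.coeffs[0])

    def __call__(self, r) -> np.ndarray:
        return np.polynomial.polynomial.polyval(r, self.coeffs)


@dataclass
class GaussianFit:
    params: np.ndarray = field(default_factory=lambda: np.zeros(4))  # G0..G3
    sigma: np.ndarray = field(default_factory=lambda: np.zeros(4))
    see: float = 0.0
    chi2: float = 0.0
    converged: bool = False
    iterations: int = 0

    @property
    def G0(self) -> float:
        return float(self.params[0])

    def __call__(self, r) -> np.ndarray:
        g0, g1, g2, g3 = self.params
        return g0 * np.exp(-(((np.asarray(r, float) - g1) / g2) ** 2)) + g3


@dataclass
class FitQuality:
    see: float
    chi2: float
    error_ratio: float  # max over coefficients of sigma(coef)/|coef|


# ---------------------------------------------------------------------------
# polar transform
# ---------------------------------------------------------------------------

def _center_offset(sample: ROISample):
    """Fit center in offset coordinates: max voxel for automatic ROIs, the
    geometric ROI center for manually placed ones.  Ties on the maximum go to
    the lowest (row, col)."""
    if sample.spec.manually_placed:
        return np.zeros(2)
    v = sample.values
    order = np.lexsort((sample.offsets[:, 1], sample.offsets[:, 0], -v))
    return sample.offsets[order[0]].copy()


def to_radial(sample: ROISample, mode: str = "unsigned") -> RadialProfile:
    """Transform an ROI sample to a radial profile about its fit center.

    ``mode="signed"`` assigns radii a sign by column offset from the center
    (right positive, left negative; on-column pixels take the row sign) for
    Gaussian fitting.
    """
    if sample.n == 0:
        raise ValueError("empty sample")
    if mode not in {"unsigned", "signed"}:
        raise ValueError(f"unknown mode {mode!r}")
    center = _center_offset(sample)
    d = sample.offsets - center
    r = np.hypot(d[:, 0], d[:, 1])
    if mode == "signed":
        sign = np.sign(d[:, 1])
        rowsign = np.sign(d[:, 0])
        sign = np.where(sign == 0, np.where(rowsign == 0, 1.0, rowsign), sign)
        r = r * sign
    return RadialProfile(r=r, values=sample.values.copy(), signed=(mode == "signed"))


def bin_profile(r: np.ndarray, values: np.ndarray):
    """Angle-average a profile: mean value per distinct radius.

    Pixels at the same radius sample the same ring at different angles; a
    genuine radial pattern reinforces across angles while incoherent noise
    averages away, so the binned profile is what the curve fits see by
    default.  Returns (radii, means, multiplicities) sorted by radius.
    """
    rr = np.round(np.asarray(r, float), 9)
    uniq, inverse, counts = np.unique(rr, return_inverse=True, return_counts=True)
    sums = np.zeros(len(uniq))
    np.add.at(sums, inverse, np.asarray(values, float))
    return uniq, sums / counts, counts


# ---------------------------------------------------------------------------
# chi-square convention
# ---------------------------------------------------------------------------

def _chi2(values: np.ndarray, model: np.ndarray) -> float:
    """Poisson-style goodness of fit: sum of resid^2 / max(y, 1)."""
    w = 1.0 / np.maximum(values, 1.0)
    return float(np.sum(w * (values - model) ** 2))


# ---------------------------------------------------------------------------
# polynomial fit (linear least squares, one step)
# ---------------------------------------------------------------------------

def fit_polynomial(
    profile: RadialProfile,
    binned: bool = False,
    sigma_mode: str = "data-noise",
) -> PolynomialFit:
    """Ordinary least squares for the cubic radial model.

    Fits every pixel individually by default; ``binned=True`` fits the
    angle-averaged profile (one point per distinct radius) instead.
    Requires at least 5 distinct radii; a singular normal matrix yields a
    non-converged fit (all downstream metrics 0).  SEE is sqrt(RSS/(n-4)).

    Coefficient uncertainties sigma(F_N): with ``sigma_mode="data-noise"``
    (default) the per-point measurement error is taken from the counting
    noise of the data itself — variance approximately the mean count — so
    sigma is the unscaled sqrt of the inverse normal matrix diagonal times
    sqrt(mean counts).  ``sigma_mode="residual"`` scales by the fit SEE
    instead.
    """
    r = np.abs(profile.r)
    y = profile.values
    if binned:
        r, y, _ = bin_profile(r, y)
    n = len(r)
    if n < 5 or len(np.unique(r)) < 5:
        return PolynomialFit()
    X = np.vander(r, 4, increasing=True)
    xtx = X.T @ X
    try:
        cov_unscaled = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return PolynomialFit()
    if np.linalg.cond(xtx) > 1e12:
        return PolynomialFit()
    coeffs = cov_unscaled @ (X.T @ y)
    resid = y - X @ coeffs
    rss = float(resid @ resid)
    see = math.sqrt(rss / (n - 4))
    if sigma_mode == "residual":
        scale = see
    elif sigma_mode == "data-noise":
        scale = math.sqrt(float(np.mean(np.maximum(y, 1.0))))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    sigma = np.sqrt(np.clip(np.diag(cov_unscaled), 0.0, None)) * scale
    return PolynomialFit(
        coeffs=coeffs,
        sigma=sigma,
        see=see,
        chi2=_chi2(y, X @ coeffs),
        converged=True,
    )


def poly_metrics(
    fit: PolynomialFit,
    r_max: float,
    snr_mode: str = "amplitude",
):
    """Polynomial-fit contrast and SNR.

    contrast = (F0 - F(r_max)) / (F0 + F(r_max)); SNR defaults to the
    amplitude form ((F0 - F(r_max))/sigma(F0))^2, with ``snr_mode="intercept"``
    giving the plain (F0/sigma(F0))^2.  A non-converged fit returns zeros.
    """
    if not fit.converged:
        return 0.0, 0.0
    f0 = fit.F0
    f_rmax = float(fit(r_max))
    denom = f0 + f_rmax
    if denom <= 0:
        logger.warning("polynomial contrast undefined (F0 + F(r_max) <= 0); set to 0")
        contrast = 0.0
    else:
        contrast = (f0 - f_rmax) / denom
    s0 = float(fit.sigma[0])
    if s0 <= 0:
        snr = 0.0
    elif snr_mode == "intercept":
        snr = (f0 / s0) ** 2
    elif snr_mode == "amplitude":
        snr = ((f0 - f_rmax) / s0) ** 2 * math.copysign(1.0, f0 - f_rmax)
        snr = max(snr, 0.0)
    else:
        raise ValueError(f"unknown snr_mode {snr_mode!r}")
    return float(contrast), float(snr)


def raw_contrast(sample: ROISample) -> float:
    """Raw image contrast (max - min)/(max + min) of the ROI values."""
    if sample.n == 0:
        raise ValueError("empty sample")
    vmax = float(sample.values.max())
    vmin = float(sample.values.min())
    if vmax + vmin <= 0:
        return 0.0
    return (vmax - vmin) / (vmax + vmin)


# ---------------------------------------------------------------------------
# Gaussian fit (gradient-expansion / Levenberg-Marquardt)
# ---------------------------------------------------------------------------

def _gauss_model_jac(r, p):
    g0, g1, g2, g3 = p
    u = (r - g1) / g2
    e = np.exp(-(u**2))
    model = g0 * e + g3
    J = np.empty((len(r), 4))
    J[:, 0] = e
    J[:, 1] = g0 * e * 2.0 * u / g2
    J[:, 2] = g0 * e * 2.0 * u**2 / g2
    J[:, 3] = 1.0
    return model, J


def fit_gaussian(
    profile: RadialProfile,
    max_iter: int = 20,
    chi2_tol: float = 1e-3,
    binned: bool = False,
) -> GaussianFit:
    """Iterative least squares for the signed-radius Gaussian model.

    Deterministic initialization: G0 = max - median, G1 = 0, G2 = 2 px,
    G3 = median.  Iterates a damped gradient-expansion step at most
    ``max_iter`` times and declares convergence when successive chi-square
    values differ by less than ``chi2_tol``.  Divergence, a singular
    Jacobian, or a non-physical width (G2 <= 0 or wider than the profile)
    yields ``converged=False`` — never an exception.
    """
    r = profile.r
    y = profile.values
    if binned:
        r, y, _ = bin_profile(r, y)
    n = len(r)
    if n < 5:
        return GaussianFit()
    med = float(np.median(y))
    p = np.array([float(y.max()) - med, 0.0, 2.0, med])
    if p[0] <= 0:
        p[0] = max(1e-3, float(y.max() - y.min()) or 1e-3)
    w = 1.0 / np.maximum(y, 1.0)

    model, _ = _gauss_model_jac(r, p)
    chi2 = float(np.sum(w * (y - model) ** 2))
    lam = 1e-3
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        model, J = _gauss_model_jac(r, p)
        resid = y - model
        A = J.T @ (J * w[:, None])
        g = J.T @ (w * resid)
        try:
            step = np.linalg.solve(A + lam * np.diag(np.diag(A)), g)
        except np.linalg.LinAlgError:
            return GaussianFit(params=p, iterations=iterations)
        p_new = p + step
        if abs(p_new[2]) < 1e-6:
            p_new[2] = 1e-6
        model_new, _ = _gauss_model_jac(r, p_new)
        chi2_new = float(np.sum(w * (y - model_new) ** 2))
        if not np.isfinite(chi2_new):
            return GaussianFit(params=p, iterations=iterations)
        if chi2_new <= chi2:
            lam = max(lam / 10.0, 1e-12)
            delta = chi2 - chi2_new
            p, chi2 = p_new, chi2_new
            if delta < chi2_tol:
                converged = True
                break
        else:
            lam *= 10.0
            if lam > 1e10:
                break

    if converged:
        # final undamped Gauss-Newton polish: the chi-square-change rule can
        # trigger a step before the parameters settle; these deterministic
        # refinements do not alter the convergence decision
        for _ in range(3):
            model, J = _gauss_model_jac(r, p)
            A = J.T @ (J * w[:, None])
            g = J.T @ (w * (y - model))
            try:
                step = np.linalg.solve(A + 1e-12 * np.diag(np.diag(A)), g)
            except np.linalg.LinAlgError:
                break
            p_new = p + step
            if abs(p_new[2]) < 1e-6 or not np.all(np.isfinite(p_new)):
                break
            model_new, _ = _gauss_model_jac(r, p_new)
            chi2_new = float(np.sum(w * (y - model_new) ** 2))
            if not np.isfinite(chi2_new) or chi2_new > chi2 * (1 + 1e-9):
                break
            p, chi2 = p_new, chi2_new

    p[2] = abs(p[2])  # width enters squared; canonicalize the sign
    r_span = float(np.abs(r).max())
    if not converged or p[2] <= 1e-6 or p[2] > 5.0 * r_span or not np.all(np.isfinite(p)):
        return GaussianFit(params=p, iterations=iterations)

    model, J = _gauss_model_jac(r, p)
    resid = y - model
    rss = float(resid @ resid)
    see = math.sqrt(rss / (n - 4)) if n > 4 else 0.0
    A = J.T @ (J * w[:, None])
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return GaussianFit(params=p, iterations=iterations)
    dof = max(n - 4, 1)
    sigma = np.sqrt(np.clip(np.diag(cov), 0.0, None) * chi2 / dof)
    return GaussianFit(
        params=p,
        sigma=sigma,
        see=see,
        chi2=chi2,
        converged=True,
        iterations=iterations,
    )


def gauss_metrics(fit: GaussianFit):
    """Gaussian-fit contrast, SNR and integral (zeros when non-converged).

    contrast = (G0 - G3)/(G0 + G3); SNR = (G0/sigma(G0))^2;
    integral = (G0 - G3) * G2.
    """
    if not fit.converged:
        return 0.0, 0.0, 0.0
    g0, _g1, g2, g3 = (float(v) for v in fit.params)
    if g0 + g3 <= 0:
        logger.warning("Gaussian contrast undefined (G0 + G3 <= 0); set to 0")
        contrast = 0.0
    else:
        contrast = (g0 - g3) / (g0 + g3)
    s0 = float(fit.sigma[0])
    snr = (g0 / s0) ** 2 if s0 > 0 else 0.0
    integral = (g0 - g3) * g2
    return float(contrast), float(snr), float(integral)


def fit_quality(fit) -> FitQuality:
    """SEE, chi-square and the worst coefficient-error ratio of a fit."""
    coeffs = fit.coeffs if isinstance(fit, PolynomialFit) else fit.params
    nonzero = np.abs(coeffs) > 1e-12
    if fit.converged and np.any(nonzero):
        ratio = float(np.max(fit.sigma[nonzero] / np.abs(coeffs[nonzero])))
    else:
        ratio = 0.0
    return FitQuality(see=float(fit.see), chi2=float(fit.chi2), error_ratio=ratio)
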