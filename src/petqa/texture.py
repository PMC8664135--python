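"""Quantile-quantile, gray-level co-occurrence and histogram metrics.

These metric families ask whether ROI voxel values deviate from what a
uniform noise region would produce, without assuming a radial lesion shape:

* Q-Q — quantiles of the target ROI values plotted against quantiles of a
  background ROI lie on the unity line when both are draws from the same
  distribution; a hot insert lifts the upper tail, so a least-squares line
  through the upper half of the curve acquires slope > 1 and/or a nonzero
  intercept;
* GLCM — co-occurrence counts of quantized gray levels within a 1-pixel
  2D neighborhood summarize local texture (energy, entropy, inertia,
  homogeneity, correlation); features are normalized per phantom to the
  highest value among its hot-insert and background ROIs;
* histogram — sample moments (mean, variance, Fisher skewness, excess
  kurtosis) plus the operational SUV ratios: max and mean ROI voxel value
  over the central background ROI mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .localize import ROISample

logger = logging.getLogger("petqa")

__all__ = [
    "QQResult",
    "GLCMFeatures",
    "HistogramFeatures",
    "GLCM_FEATURE_NAMES",
    "qq_metrics",
    "glcm_features",
    "normalize_features",
    "histogram_features",
]

GLCM_FEATURE_NAMES = ("energy", "entropy", "inertia", "homogeneity", "correlation")

#: 1-pixel 2D neighborhood: the four unique symmetric offsets (E, S, SE, SW).
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class QQResult:
    background_q: np.ndarray
    target_q: np.ndarray
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_deviates: bool
    intercept_deviates: bool
    alpha: float


@dataclass
class GLCMFeatures:
    energy: float
    entropy: float
    inertia: float
    homogeneity: float
    correlation: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in GLCM_FEATURE_NAMES}


@dataclass
class HistogramFeatures:
    mean: float
    variance: float
    skewness: float
    kurtosis: float  # excess (normal -> 0)
    suv_max: float
    suv_mean: float


# ---------------------------------------------------------------------------
# Q-Q
# ---------------------------------------------------------------------------

def qq_metrics(
    target: ROISample,
    background: ROISample,
    alpha: float = 0.05,
) -> QQResult:
    """Upper-half Q-Q regression of target quantiles on background quantiles.

    Samples of unequal size are interpolated onto min(n_t, n_b) evenly
    spaced quantiles.  Deviation flags come from t-tests of slope = 1 and
    intercept = 0 using the regression standard errors.
    """
    t = np.sort(np.asarray(target.values, float))
    b = np.sort(np.asarray(background.values, float))
    if len(t) < 10 or len(b) < 10:
        raise ValueError("both samples need at least 10 values")
    if float(b.max() - b.min()) == 0.0:
        raise ValueError("background sample has zero variance; Q-Q slope undefined")
    m = min(len(t), len(b))
    probs = np.linspace(0.0, 1.0, m)
    tq = np.quantile(t, probs) if len(t) != m else t
    bq = np.quantile(b, probs) if len(b) != m else b

    upper = bq >= np.median(bq)  # inclusive on ties
    x, y = bq[upper], tq[upper]
    k = len(x)
    if k < 3 or float(x.max() - x.min()) == 0.0:
        raise ValueError("upper-half background quantiles are degenerate")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    slope_se, intercept_se = float(res.stderr), float(res.intercept_stderr)

    def deviates(estimate: float, null: float, se: float) -> bool:
        if se == 0.0:
            return estimate != null
        tstat = (estimate - null) / se
        p = 2.0 * stats.t.sf(abs(tstat), df=k - 2)
        return bool(p < alpha)

    return QQResult(
        background_q=bq,
        target_q=tq,
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        slope_deviates=deviates(slope, 1.0, slope_se),
        intercept_deviates=deviates(intercept, 0.0, intercept_se),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _sample_to_patch(sample: ROISample):
    """Rebuild the 2D ROI patch; pixels outside the circular ROI are NaN."""
    rows = np.round(sample.offsets[:, 0] - sample.offsets[:, 0].min()).astype(int)
    cols = np.round(sample.offsets[:, 1] - sample.offsets[:, 1].min()).astype(int)
    patch = np.full((rows.max() + 1, cols.max() + 1), np.nan)
    patch[rows, cols] = sample.values
    return patch


def glcm_matrix(
    patch: np.ndarray,
    levels: int = 64,
    offsets=GLCM_OFFSETS,
) -> np.ndarray:
    """Symmetrized co-occurrence probability matrix of a (masked) patch.

    The patch is quantized to ``levels`` equal-width bins over its own
    min-max range; NaN pixels (outside the circular ROI) contribute to no
    pair.  All offsets are pooled into one matrix.
    """
    valid = np.isfinite(patch)
    vals = patch[valid]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        q = np.floor((patch - vmin) / (vmax - vmin) * levels)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros_like(patch)
    q = np.where(valid, q, -1).astype(int)

    M = np.zeros((levels, levels))
    nrow, ncol = q.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        a = q[r0:r1, c0:c1]
        bsub = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (bsub >= 0)
        np.add.at(M, (a[ok], bsub[ok]), 1.0)
    M = M + M.T  # symmetrize
    total = M.sum()
    if total > 0:
        M /= total
    return M


def glcm_features(
    sample: ROISample,
    levels: int = 64,
    offsets=GLCM_OFFSETS,
) -> GLCMFeatures:
    """Haralick-style features of the pooled, symmetrized GLCM.

    A constant patch is the degenerate contract: energy 1, entropy 0,
    inertia 0, homogeneity 1, correlation 0 (zero variance).
    """
    patch = _sample_to_patch(sample)
    vals = sample.values
    if float(vals.max() - vals.min()) == 0.0:
        return GLCMFeatures(1.0, 0.0, 0.0, 1.0, 0.0)
    P = glcm_matrix(patch, levels=levels, offsets=offsets)
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    nz = P > 0
    energy = float(np.sum(P * P))
    entropy = float(-np.sum(P[nz] * np.log(P[nz])))
    inertia = float(np.sum((i - j) ** 2 * P))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * P))
    mu_j = float(np.sum(j * P))
    var_i = float(np.sum((i - mu_i) ** 2 * P))
    var_j = float(np.sum((j - mu_j) ** 2 * P))
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * P) / np.sqrt(var_i * var_j)
        )
    return GLCMFeatures(energy, entropy, inertia, homogeneity, correlation)


def normalize_features(
    table: pd.DataFrame,
    columns=GLCM_FEATURE_NAMES,
    reference_labels=None,
    label_col: str = "roi_label",
) -> pd.DataFrame:
    """Per-phantom normalization: divide each feature by its maximum across
    the phantom's ROIs (optionally restricted to ``reference_labels``, e.g.
    the hot-insert and background ROIs).  The maximum maps to exactly 1;
    an all-zero column is left at 0 with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 ROIs per phantom to normalize")
    out = table.copy()
    ref = table
    if reference_labels is not None:
        ref = table[table[label_col].isin(reference_labels)]
        if ref.empty:
            ref = table
    for col in columns:
        top = float(ref[col].abs().max())
        if top == 0.0:
            logger.warning("feature %s is all-zero; left unnormalized", col)
            continue
        out[col] = table[col] / top
    return out


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def histogram_features(sample: ROISample, background_ref: float) -> HistogramFeatures:
    """Moments of the ROI value distribution plus max/mean SUV ratios.

    ``background_ref`` is the mean voxel value of the central background ROI
    (per pixel), so a background ROI referenced to its own mean has
    suv_mean exactly 1.  Variance uses the n-1 denominator; skewness is
    Fisher g1 and kurtosis is excess g2.
    """
    v = np.asarray(sample.values, float)
    if len(v) < 4:
        raise ValueError("kurtosis needs at least 4 values")
    if background_ref <= 0:
        raise ValueError("background reference must be positive")
    return HistogramFeatures(
        mean=float(v.mean()),
        variance=float(v.var(ddof=1)),
        skewness=float(stats.skew(v, bias=True)),
        kurtosis=float(stats.kurtosis(v, fisher=True, bias=True)),
        suv_max=float(v.max() / background_ref),
        suv_mean=float(v.mean() / background_ref),
    )
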