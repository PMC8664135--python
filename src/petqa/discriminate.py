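"""ROC discrimination, reader agreement and group-comparison statistics.

Each detectability metric is evaluated as a classifier score for two tasks:
agreement with reader visibility labels, and ground-truth cylinder-versus-
background discrimination.  The empirical (trapezoidal) ROC is used, with
the Hanley-McNeil standard error, Youden-optimal operating threshold, and
the paired DeLong test for AUC differences between metrics scored on the
same observations.  Reader agreement uses unweighted Cohen's kappa with the
conventional strength bands; group comparisons gate on a normality test to
choose between parametric (t/ANOVA) and nonparametric (Mann-Whitney /
Wilcoxon / Kruskal-Wallis) procedures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score, roc_curve

__all__ = [
    "LabeledScores",
    "ROCResult",
    "KappaResult",
    "roc_analysis",
    "compare_auc",
    "cohen_kappa",
    "kappa_strength",
    "visibility_truth",
    "group_compare",
]


@dataclass
class LabeledScores:
    """Per-observation metric values with binary labels (positive = cylinder
    or visible)."""

    scores: np.ndarray
    labels: np.ndarray
    phantom_ids: np.ndarray | None = None
    roi_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must align")
        if self.labels.min() == self.labels.max():
            raise ValueError("need at least one positive and one negative")


@dataclass
class ROCResult:
    auc: float
    auc_se: float
    orientation: int  # +1 if higher score indicates positive
    optimal_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def threshold_str(self) -> str:
        op = ">" if self.orientation > 0 else "<"
        return f"{op}{self.optimal_threshold:g}"


@dataclass
class KappaResult:
    kappa: float
    strength: str
    n: int


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_analysis(data: LabeledScores) -> ROCResult:
    """Empirical ROC with Youden-optimal operating point.

    Orientation is chosen so AUC >= 0.5 and recorded (+1: higher score is
    positive).  Threshold ties on Youden's J resolve toward higher
    specificity.  The reported sensitivity/specificity are exactly
    reproducible by applying ``orientation * score >= orientation *
    threshold`` to the input data.
    """
    y = data.labels
    auc = float(roc_auc_score(y, data.scores))
    orientation = 1 if auc >= 0.5 else -1
    scores = data.scores * orientation
    if orientation < 0:
        auc = 1.0 - auc

    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))  # first occurrence = lowest fpr = highest specificity
    thr = float(thresholds[best])
    if not np.isfinite(thr):  # sklearn's +inf sentinel above the top score
        thr = float(scores.max()) + 1.0

    pred = scores >= thr
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return ROCResult(
        auc=auc,
        auc_se=_hanley_mcneil_se(auc, n_pos, n_neg),
        orientation=orientation,
        optimal_threshold=thr * orientation,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        accuracy=(tp + tn) / len(y),
    )


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = v10.mean()
    return auc, v10, v01


def compare_auc(a: LabeledScores, b: LabeledScores) -> float:
    """Two-sided p-value of the paired DeLong test for AUC(a) != AUC(b).

    Both score sets must be computed on the identical observations (same
    labels in the same order; phantom ids are checked when present).
    """
    if len(a.scores) != len(b.scores) or not np.array_equal(a.labels, b.labels):
        raise ValueError("paired comparison requires identical observations")
    if a.phantom_ids is not None and b.phantom_ids is not None:
        if not np.array_equal(a.phantom_ids, b.phantom_ids):
            raise ValueError("paired comparison requires identical phantoms")

    # scores are compared in the orientation given; re-orienting each metric
    # toward AUC >= 0.5 here would fold the null distribution and make the
    # test conservative, so callers flip direction-reversed metrics (e.g. via
    # roc_analysis.orientation) before comparing
    (auc_a, v10_a, v01_a) = _delong_placements(a.scores, a.labels)
    (auc_b, v10_b, v01_b) = _delong_placements(b.scores, b.labels)

    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# reader agreement
# ---------------------------------------------------------------------------

_KAPPA_BANDS = ((0.20, "poor"), (0.40, "fair"), (0.60, "moderate"), (0.80, "good"))


def kappa_strength(kappa: float) -> str:
    for cut, name in _KAPPA_BANDS:
        if kappa <= cut:
            return name
    return "very good"


def cohen_kappa(r1, r2, scale: str = "five_level") -> KappaResult:
    """Unweighted Cohen's kappa between two raters on the stated scale."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if len(r1) != len(r2):
        raise ValueError("ratings must be paired")
    if scale == "dichotomous":
        r1 = (r1 > 0).astype(int) if r1.max() > 1 else r1.astype(int)
        r2 = (r2 > 0).astype(int) if r2.max() > 1 else r2.astype(int)
    if len(np.unique(np.concatenate([r1, r2]))) < 2:
        raise ValueError("kappa undefined: a single category was used")
    k = float(cohen_kappa_score(r1, r2))
    if math.isnan(k):
        raise ValueError("kappa undefined for these ratings")
    return KappaResult(kappa=k, strength=kappa_strength(k), n=len(r1))


def visibility_truth(records: pd.DataFrame) -> pd.DataFrame:
    """Mean reader score per (phantom, ROI); visible iff mean > 1 (strict).

    ``records`` columns: phantom_id, roi_label, reader_id, score (0-4).
    """
    grouped = (
        records.groupby(["phantom_id", "roi_label"])["score"].mean().reset_index()
    )
    grouped = grouped.rename(columns={"score": "mean_score"})
    grouped["visible"] = grouped["mean_score"] > 1.0
    return grouped


# ---------------------------------------------------------------------------
# group comparison with normality gate
# ---------------------------------------------------------------------------

def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if len(x) >= 8:
        p = stats.normaltest(x).pvalue  # D'Agostino-Pearson chi-square omnibus
    else:
        p = stats.shapiro(x).pvalue
    return bool(p >= alpha)


def group_compare(
    values,
    groups=None,
    design: str = "independent",
    alpha: float = 0.05,
):
    """Compare >= 2 groups, gating parametric vs nonparametric on normality.

    ``values`` is either a list of arrays, or a flat array with ``groups``
    labels.  Returns ``(p_value, test_name)``.
    """
    if groups is not None:
        values = np.asarray(values, float)
        labels = np.asarray(groups)
        samples = [values[labels == g] for g in pd.unique(labels)]
    else:
        samples = [np.asarray(v, float) for v in values]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 3 for s in samples):
        raise ValueError("each group needs at least 3 observations")

    normal = all(_is_normal(s, alpha) for s in samples)
    if len(samples) == 2:
        a, b = samples
        if design == "paired":
            if len(a) != len(b):
                raise ValueError("paired design requires equal-length groups")
            if normal:
                return float(stats.ttest_rel(a, b).pvalue), "paired t-test"
            if np.allclose(a, b):
                return 1.0, "Wilcoxon"
            return float(stats.wilcoxon(a, b).pvalue), "Wilcoxon"
        if normal:
            return float(stats.ttest_ind(a, b).pvalue), "unpaired t-test"
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), "Mann-Whitney"
    if normal:
        return float(stats.f_oneway(*samples).pvalue), "ANOVA"
    return float(stats.kruskal(*samples).pvalue), "Kruskal-Wallis"
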