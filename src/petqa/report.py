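"""End-to-end QA workflow: per-phantom analysis and cohort ROC studies.

``analyze_phantom`` composes the full per-scan pipeline — normalize, find the
hot slice, generate/recenter the eight ROIs (honoring manual overrides),
extract samples and compute every detectability metric — into one
JSON-serializable report fragment.  ``run_study`` pools fragments across a
cohort into per-metric labeled score sets and produces the ROC tables for
the cylinder-versus-background and visibility-agreement tasks, plus reader
kappa summaries when visibility scores are supplied.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import discriminate as dsc
from . import localize as loc
from . import radial as rad
from . import texture as tex
from .core import PhantomVolume, load_volume, normalize_volume
from .simulate import AcquisitionConfig, PhantomGeometry, simulate_cohort

logger = logging.getLogger("petqa")

__all__ = [
    "HEADLINE_METRICS",
    "analyze_phantom",
    "run_study",
    "run_simulated_study",
    "metrics_dataframe",
    "scores_for_task",
]

#: Score metrics evaluated in the ROC tables (sign handled by orientation).
HEADLINE_METRICS = (
    "poly_contrast",
    "poly_snr",
    "raw_contrast",
    "gauss_snr",
    "gauss_integral",
    "qq_slope",
    "qq_intercept",
    "hist_skewness",
    "suv_max",
)

HOT_LABELS = ("hot-25", "hot-16", "hot-12", "hot-8")

#: Emulates the reader check of the 8-mm ROI: if automatic recentering moved
#: it farther than this from the a priori position, it is re-placed there
#: manually (fit then centers on the ROI center, not a local maximum).
AUTO_OVERRIDE_8MM_MM = 6.0


def _roi_metrics(
    sample: loc.ROISample,
    reference_bg: loc.ROISample,
    background_ref_mean: float,
) -> dict:
    """All per-ROI metrics for one 40-mm ROI."""
    out: dict = {}

    profile = rad.to_radial(sample, mode="unsigned")
    pfit = rad.fit_polynomial(profile)
    contrast, snr = rad.poly_metrics(pfit, profile.r_max)
    pq = rad.fit_quality(pfit)
    out.update(
        poly_contrast=contrast,
        poly_snr=snr,
        poly_see=pq.see,
        poly_chi2=pq.chi2,
        poly_error_ratio=pq.error_ratio,
        poly_converged=bool(pfit.converged),
    )

    signed = rad.to_radial(sample, mode="signed")
    gfit = rad.fit_gaussian(signed)
    gcontrast, gsnr, gintegral = rad.gauss_metrics(gfit)
    gq = rad.fit_quality(gfit)
    out.update(
        gauss_contrast=gcontrast,
        gauss_snr=gsnr,
        gauss_integral=gintegral,
        gauss_see=gq.see,
        gauss_chi2=gq.chi2,
        gauss_error_ratio=gq.error_ratio,
        gauss_converged=bool(gfit.converged),
        gauss_iterations=int(gfit.iterations),
    )

    out["raw_contrast"] = rad.raw_contrast(sample)

    qq = tex.qq_metrics(sample, reference_bg)
    out.update(
        qq_slope=qq.slope,
        qq_intercept=qq.intercept,
        qq_slope_deviates=bool(qq.slope_deviates),
        qq_intercept_deviates=bool(qq.intercept_deviates),
    )

    glcm = tex.glcm_features(sample)
    out.update({f"glcm_{k}": v for k, v in glcm.as_dict().items()})

    hist = tex.histogram_features(sample, background_ref_mean)
    out.update(
        hist_mean=hist.mean,
        hist_variance=hist.variance,
        hist_skewness=hist.skewness,
        hist_kurtosis=hist.kurtosis,
        suv_max=hist.suv_max,
        suv_mean=hist.suv_mean,
    )
    return out


def analyze_phantom(
    source,
    geometry: PhantomGeometry | None = None,
    overrides: dict | None = None,
    reference_slice: int | None = None,
    truth=None,
    auto_override_8mm_mm: float | None = None,
) -> dict:
    """Run the whole single-phantom pipeline; returns a report fragment.

    ``source`` is a PhantomVolume or a path loadable by ``load_volume``.
    ``overrides`` maps ROI labels to manual (row, col) centers.  The Q-Q
    reference background sample is taken from ``reference_slice`` (default:
    the end slice farthest from the hot slice, which lies in the uniform
    section).  With simulated ``truth``, the a priori 8-mm position for the
    automatic-override check comes from the truth geometry; per-ROI errors
    are recorded in the fragment without aborting the remaining ROIs.
    """
    if auto_override_8mm_mm is None:
        auto_override_8mm_mm = AUTO_OVERRIDE_8MM_MM
    geometry = geometry or PhantomGeometry()
    vol = source if isinstance(source, PhantomVolume) else load_volume(source)
    if not vol.normalized:
        vol = normalize_volume(vol)

    hot_slice = loc.find_hot_slice(vol)
    slice2d = vol.get_slice(hot_slice)
    p = vol.pixel_size_mm

    fragment: dict = {
        "source_id": vol.source_id,
        "pixel_size_mm": p,
        "slice_thickness_mm": vol.slice_thickness_mm,
        "hot_slice": hot_slice,
        "rois": [],
        "metrics": {},
        "errors": [],
    }
    if truth is not None:
        fragment["hot_slice_in_truth"] = bool(hot_slice in set(truth.hot_slices))

    rois = loc.generate_rois(slice2d, geometry, p)
    apriori = {r.label: r.center for r in rois}
    processed = []
    for roi in rois:
        if roi.label.startswith("hot"):
            roi = loc.recenter_roi(slice2d, roi, p)
        if roi.label == "hot-8" and auto_override_8mm_mm is not None:
            prior = apriori["hot-8"]
            if truth is not None and "hot-8" in truth.centers_px:
                prior = truth.centers_px["hot-8"]
            moved = math.hypot(roi.center[0] - prior[0], roi.center[1] - prior[1]) * p
            if moved > auto_override_8mm_mm:
                roi = loc.override_roi(roi, prior, slice2d)
        if overrides and roi.label in overrides:
            roi = loc.override_roi(roi, overrides[roi.label], slice2d)
        processed.append(roi)

    # Q-Q reference: a background ROI from the uniform section
    if reference_slice is None:
        reference_slice = vol.n_slices - 1 if hot_slice < vol.n_slices / 2 else 0
    ref2d = vol.get_slice(reference_slice)
    bg_roi = next(r for r in processed if r.label == loc.BACKGROUND_LABEL)
    ref_sample = loc.extract_samples(ref2d, bg_roi, p)
    fragment["reference_slice"] = reference_slice

    bg_sample = loc.extract_samples(slice2d, bg_roi, p)
    bg_mean = float(bg_sample.values.mean())
    fragment["background_mean"] = bg_mean

    for roi in processed:
        fragment["rois"].append(
            {
                "label": roi.label,
                "center": [float(roi.center[0]), float(roi.center[1])],
                "diameter_mm": roi.diameter_mm,
                "manually_placed": roi.manually_placed,
            }
        )
        try:
            sample = loc.extract_samples(slice2d, roi, p)
            fragment["metrics"][roi.label] = _roi_metrics(sample, ref_sample, bg_mean)
        except Exception as exc:  # noqa: BLE001 - keep processing other ROIs
            logger.warning("ROI %s failed on %s: %s", roi.label, vol.source_id, exc)
            fragment["errors"].append({"roi": roi.label, "error": str(exc)})

    # per-phantom GLCM normalization over the hot-insert and background ROIs
    glcm_cols = [f"glcm_{k}" for k in tex.GLCM_FEATURE_NAMES]
    table = pd.DataFrame(
        [
            {"roi_label": lab, **{c: m[c] for c in glcm_cols}}
            for lab, m in fragment["metrics"].items()
        ]
    )
    if len(table) >= 2:
        normed = tex.normalize_features(
            table,
            columns=glcm_cols,
            reference_labels=list(HOT_LABELS) + [loc.BACKGROUND_LABEL],
        )
        for _, row in normed.iterrows():
            for c in glcm_cols:
                fragment["metrics"][row["roi_label"]][c + "_norm"] = float(row[c])
    return fragment


def fragment_to_json(fragment: dict) -> str:
    """Deterministic JSON encoding of a report fragment."""
    return json.dumps(fragment, sort_keys=True, indent=1, allow_nan=True)


def metrics_dataframe(fragments) -> pd.DataFrame:
    """Long table: one row per ROI per phantom with every metric column."""
    rows = []
    for frag in fragments:
        for lab, metrics in frag["metrics"].items():
            rows.append(
                {"phantom_id": frag["source_id"], "roi_label": lab, **metrics}
            )
    return pd.DataFrame(rows)


def scores_for_task(
    df: pd.DataFrame,
    metric: str,
    task: str,
    visibility: pd.DataFrame | None = None,
) -> dsc.LabeledScores:
    """Build the labeled score set for one metric and one study task.

    Tasks: ``"truth-8mm"`` (8-mm cylinders vs background), ``"truth-all"``
    (all four cylinders vs background), ``"visibility"`` (hot-insert and
    background ROIs labeled by mean reader score > 1).
    """
    if task == "truth-8mm":
        sub = df[df["roi_label"].isin(["hot-8", loc.BACKGROUND_LABEL])]
        labels = (sub["roi_label"] == "hot-8").to_numpy()
    elif task == "truth-all":
        sub = df[df["roi_label"].isin(list(HOT_LABELS) + [loc.BACKGROUND_LABEL])]
        labels = sub["roi_label"].isin(HOT_LABELS).to_numpy()
    elif task == "visibility":
        if visibility is None:
            raise ValueError("visibility task requires reader records")
        truth = dsc.visibility_truth(visibility)
        sub = df.merge(truth, on=["phantom_id", "roi_label"], how="inner")
        labels = sub["visible"].to_numpy()
    else:
        raise ValueError(f"unknown task {task!r}")
    return dsc.LabeledScores(
        scores=sub[metric].to_numpy(float),
        labels=labels.astype(int),
        phantom_ids=sub["phantom_id"].to_numpy(),
        roi_labels=sub["roi_label"].to_numpy(),
    )


def _roc_table(df, task, metrics, visibility=None) -> list[dict]:
    rows = []
    for metric in metrics:
        data = scores_for_task(df, metric, task, visibility)
        roc = dsc.roc_analysis(data)
        pos = data.scores[data.labels == 1]
        neg = data.scores[data.labels == 0]
        rows.append(
            {
                "metric": metric,
                "n": int(len(data.scores)),
                "auc_pct": roc.auc * 100.0,
                "auc_se_pct": roc.auc_se * 100.0,
                "sensitivity_pct": roc.sensitivity * 100.0,
                "specificity_pct": roc.specificity * 100.0,
                "accuracy_pct": roc.accuracy * 100.0,
                "threshold": roc.threshold_str,
                "positive_mean": float(pos.mean()),
                "positive_sd": float(pos.std(ddof=1)) if len(pos) > 1 else 0.0,
                "negative_mean": float(neg.mean()),
                "negative_sd": float(neg.std(ddof=1)) if len(neg) > 1 else 0.0,
            }
        )
    rows.sort(key=lambda r: -r["auc_pct"])
    return rows


def run_study(
    fragments,
    visibility: pd.DataFrame | None = None,
    metrics=HEADLINE_METRICS,
) -> dict:
    """Pool per-phantom fragments into the cohort-level QA report.

    Always produces the ground-truth discrimination tables (all-cylinder and
    8-mm tasks); with reader ``visibility`` records also the visibility-
    agreement table and inter-reader kappa summaries.
    """
    fragments = list(fragments)
    if len(fragments) < 2:
        raise ValueError("need at least 2 phantoms for a study")
    df = metrics_dataframe(fragments)
    report: dict = {
        "n_phantoms": len(fragments),
        "roc_tables": {
            "truth-all": _roc_table(df, "truth-all", metrics),
            "truth-8mm": _roc_table(df, "truth-8mm", metrics),
        },
        "gauss_nonconvergence": {
            lab: float(1.0 - grp["gauss_converged"].mean())
            for lab, grp in df.groupby("roi_label")
        },
    }
    if "hot_slice_in_truth" in fragments[0]:
        hits = [bool(f.get("hot_slice_in_truth")) for f in fragments]
        report["hot_slice_success_rate"] = float(np.mean(hits))

    if visibility is not None:
        report["roc_tables"]["visibility"] = _roc_table(
            df, "visibility", metrics, visibility
        )
        readers = sorted(visibility["reader_id"].unique())
        if len(readers) >= 2:
            wide = visibility.pivot_table(
                index=["phantom_id", "roi_label"],
                columns="reader_id",
                values="score",
            ).dropna()
            r1, r2 = wide[readers[0]].to_numpy(), wide[readers[1]].to_numpy()
            report["kappa"] = {
                "five_level": vars(dsc.cohen_kappa(r1, r2, "five_level")),
                "dichotomous": vars(
                    dsc.cohen_kappa((r1 > 1).astype(int), (r2 > 1).astype(int), "dichotomous")
                ),
            }
    return report


def run_simulated_study(
    n: int = 65,
    master_seed: int = 7,
    geometry: PhantomGeometry | None = None,
    base_config: AcquisitionConfig | None = None,
    config_ranges: dict | None = None,
):
    """Simulate a cohort and run the full study against ground truth.

    Returns ``(report, fragments, dataframe)``.
    """
    geometry = geometry or PhantomGeometry()
    cohort = simulate_cohort(
        n,
        config_ranges=config_ranges,
        master_seed=master_seed,
        geometry=geometry,
        base_config=base_config,
    )
    fragments = [
        analyze_phantom(vol, geometry=geometry, truth=truth) for vol, truth in cohort
    ]
    report = run_study(fragments)
    return report, fragments, metrics_dataframe(fragments)
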