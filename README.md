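# petqa — small-lesion detectability metrics for PET QA phantom scans

`petqa` quantifies how reliably sub-centimeter "hot" lesions can be detected
in ¹⁸F-FDG PET quality-assurance phantom scans. It targets the standardized
flangeless Esser (Jaszczak-type) phantom: a cylindrical water bath holding
four hot cylinders of 25, 16, 12 and 8 mm internal diameter filled at a
2.5:1 activity-to-background ratio, plus three cold inserts. The question
the package answers is the clinically relevant one: **which quantitative
image metric discriminates an 8-mm hot cylinder from uniform background
noise, and how does it compare with maximum-SUV readings and visual
impressions?**

It is intended for medical physicists running PET QA programs and for
image-analysis researchers studying lesion-detectability metrics.

## What it computes

For every reconstructed phantom volume the pipeline:

1. **normalizes** the volume so the global maximum voxel is 100 (one scale
   factor for the whole 3D grid, preserving relative noise);
2. **localizes** the transaxial slice holding the global maximum and places
   eight 40-mm circular ROIs — the four hot cylinders and three cold inserts
   on their ring (rotated from the detected hottest insert by the known
   inter-insert angles) and one background ROI at the phantom center — with
   automatic re-centering on each hot cylinder's actual maximum and manual
   override hooks;
3. computes per-ROI **detectability metrics**:
   - radial curve fits about the candidate lesion center: a cubic
     F(r) = F₀ + F₁r + F₂r² + F₃r³ over unsigned radii and a Gaussian
     G(r) = G₀·exp(−((r−G₁)/G₂)²) + G₃ over signed radii, yielding

     | metric | definition |
     |---|---|
     | polynomial-fit contrast | (F₀ − F(r_max)) / (F₀ + F(r_max)) |
     | polynomial-fit SNR | ((F₀ − F(r_max)) / σ(F₀))² |
     | raw contrast | (max − min) / (max + min) |
     | Gaussian-fit contrast | (G₀ − G₃) / (G₀ + G₃) |
     | Gaussian-fit SNR | (G₀ / σ(G₀))² |
     | Gaussian integral | (G₀ − G₃) · G₂ |

     with SEE/χ²/error-ratio fit-quality reporting and metric zeroing on
     non-convergence (the Gaussian fit iterates at most 20 times to a χ²
     change below 10⁻³ — failure on flat noise is itself evidence of an
     absent signal);
   - quantile-quantile slope and intercept of the upper half of the target
     ROI's quantiles against a uniform-section background ROI;
   - GLCM texture features (energy, entropy, inertia, homogeneity,
     correlation) with per-phantom normalization;
   - histogram moments plus max/mean SUV (ROI max or mean over the central
     background ROI mean);
4. pools a cohort into **ROC analyses** (trapezoidal AUC, Hanley–McNeil SE,
   Youden-optimal thresholds, DeLong paired AUC comparisons) for
   cylinder-vs-background discrimination and agreement with reader
   visibility scores, with Cohen's kappa for reader agreement.

Because the scanner acquisitions behind the reference study are not public,
the package ships a **calibrated synthetic phantom simulator**
(`petqa.simulate`) producing reconstructed-domain scans — anti-aliased
activity maps, Gaussian post-reconstruction blur, heavy-tailed correlated
noise, residual bath non-uniformity, per-scanner parameter spreads — with
ground-truth ROI labels, so the whole pipeline is testable end to end.

## Worked example

```python
from petqa.report import run_simulated_study

report, fragments, df = run_simulated_study(n=65, master_seed=1)
```

This simulates a 65-phantom multi-scanner QA archive, analyzes every
phantom, and returns the per-ROI metric table plus ROC studies. The 8-mm
cylinder vs background table (`report["roc_tables"]["truth-8mm"]`) from
that exact call:

```
        metric  auc_pct  auc_se_pct  sensitivity_pct  specificity_pct threshold
 poly_contrast     98.3         1.1             98.5             96.9 >0.120165
      poly_snr     96.3         1.7             92.3             96.9   >6.5464
     gauss_snr     96.2         1.7             92.3            100.0   >17.971
      qq_slope     92.3         2.5             80.0             92.3  >1.26225
  qq_intercept     89.4         2.9             64.6             95.4 <-11.3397
 hist_skewness     87.0         3.2             80.0             83.1 >0.223187
       suv_max     86.5         3.3             70.8             87.7  >1.39312
gauss_integral     75.2         4.3             93.8             73.8 <-31.1036
  raw_contrast     69.0         4.6             83.1             50.8 >0.279102
```

Reading it: the polynomial-fit metrics discriminate sub-centimeter
cylinders from background far better (AUC 96–98%) than the maximum SUV
(86.5%) or the raw max–min contrast (69%), because a coherent radial
pattern survives fitting while single-pixel noise spikes — which drive
`suv_max` and `raw_contrast` — do not. A single phantom fragment shows the
same story at ROI level (first cohort phantom, hot slice 6):

```
hot-25      suv_max=2.18  poly_contrast=36.1%  poly_snr=71.9  gauss_conv=True
hot-8       suv_max=1.74  poly_contrast=15.7%  poly_snr=13.8  gauss_conv=True
background  suv_max=1.32  poly_contrast=3.0%   poly_snr=0.5   gauss_conv=False
```

The background Gaussian fit failed to converge (metrics zeroed) — expected
behavior on a signal-free ROI.

The same workflow is available from the shell:

```
petqa simulate --n 65 --seed 7 --out cohort/
petqa analyze cohort/sim-7-000.npz --out frag.json --render slabs/
petqa roc-study --cohort cohort/ --out study/
petqa report --n 65 --seed 7 --out qa_report/
```

Real scans load from DICOM series directories (`petqa analyze dicom_dir/`);
reader visibility scores join via `--visibility scores.csv` (columns
`phantom_id, roi_label, reader_id, score` on the 0–4 confidence scale; an
ROI counts as visible when the mean score exceeds 1).

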