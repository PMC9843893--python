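# pancrad

A computer-aided-detection (CAD) pipeline for pancreatic cancer on
contrast-enhanced CT, built from 2D and 3D radiomic analysis, plus the
full diagnostic-accuracy statistics layer used to evaluate such a tool.

## Who this is for

Researchers building or auditing radiomics classifiers for pancreatic
lesions: the package provides the whole chain — volume I/O and resampling,
texture feature extraction, patch/heatmap analysis, gradient-boosted
classification, logistic fusion, decision rules — together with the exact
statistics (Clopper–Pearson intervals, likelihood ratios, DeLong AUC
comparisons, trend tests) needed to report a diagnostic study. Because no
public pancreatic CT cohort ships with it, a seeded phantom generator
produces pancreas-like volumes with hypodense, texturally busy tumors so
the whole pipeline is trainable and testable offline.

## The method

A study is a CT volume plus a segmentation mask (0 background, 1 pancreas,
2 tumor), resampled to 1×1×5 mm (linear for the image, nearest-neighbour
for labels). Two branches analyse the pancreas-plus-tumor region:

* **3D branch** — first-order and texture features (GLCM, GLRLM, GLSZM,
  GLDM, NGTDM; bin width 16 HU anchored at the region minimum) on the
  original and filtered (coif1 wavelet bands, Laplacian-of-Gaussian)
  volumes feed an XGBoost classifier with logistic loss, early-stopped on
  validation AUC (patience 30). Its output is a probability *p*₃D.
* **2D branch** — each axial slice is cropped into 20×20 patches on a
  stride-5 lattice; patches with more than 5 % ROI overlap are scored by a
  patch-level XGBoost model, probabilities are averaged per pixel into a
  heatmap, and the study statistic is the area *A* (mm²) of the largest
  8-connected region of pixels exceeding a threshold *t* chosen on the
  validation cohort by scanning t ∈ {0.05, 0.06, …, 0.95} for maximal AUC.

The branches fuse through a logistic model

```
logit(p) = β₀ + β₁·p₃D + β₂·A
```

fitted on validation studies. The published operating point
(β₁ = 3.95759716, β₂ = 0.00241766494 per mm², β₀ = −2.79234888) ships as
`pancrad.REFERENCE_FUSION`. Operating cutoffs for all three scores come
from the maximal Youden index (sensitivity + specificity − 1); series
(both branches positive) and parallel (either positive) rules trade
sensitivity against specificity.

## Worked example

```python
from pancrad import diagnostics as dx
from pancrad.tables import NATIONWIDE_CROSSTAB

m = dx.accuracy_metrics(NATIONWIDE_CROSSTAB.series_counts())
print({k: v.round() for k, v in m.items()})
lr = dx.stratum_likelihood_ratios(NATIONWIDE_CROSSTAB)["3d+2d+"]
print(round(lr.point, 2), (round(lr.lower, 2), round(lr.upper, 2)))
```

prints

```
{'sensitivity': (0.742, 0.707, 0.775), 'specificity': (0.952, 0.934, 0.965), 'accuracy': (0.856, 0.837, 0.874)}
15.32 (11.24, 20.87)
```

— the series rule on the nationwide cross-tab detects 74.2 % of cancers at
95.2 % specificity, and a double-positive call multiplies the pre-test
odds of cancer by 15.3.

The same layer is reachable from the shell. A complete phantom round trip:

```bash
pancrad phantom --out cohort --cases 20 --controls 20 --seed 7
pancrad train --cohort cohort --out bundle.json --seed 7
pancrad predict --cohort cohort --bundle bundle.json --out calls.csv
pancrad evaluate --calls calls.csv --out report.json
```

## Layout

| module | role |
| --- | --- |
| `pancrad.volume` | NIfTI/DICOM reading, co-registration, resampling, ROI union |
| `pancrad.texture`, `pancrad.features` | texture matrices, feature formulas, manifests |
| `pancrad.patches`, `pancrad.heatmap` | 2D patch lattice, heatmaps, high-risk area |
| `pancrad.training` | XGBoost wrappers with AUC early stopping, gain rankings |
| `pancrad.fusion` | logistic fusion, Youden cutoffs, series/parallel decisions |
| `pancrad.diagnostics`, `pancrad.report` | exact CIs, LRs, DeLong, trend tests, reports |
| `pancrad.phantom`, `pancrad.experiment` | synthetic cohorts, end-to-end experiment |
| `pancrad.pipeline`, `pancrad.cli` | file-based stages and the `pancrad` CLI |

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
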