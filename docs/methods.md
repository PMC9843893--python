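# Methods

This note documents the modelling choices behind `pancrad`: what each stage
computes, the parameters that matter, what the synthetic phantoms do and do
not emulate, and the numerical conventions adopted where the design was
genuinely open.

## Canonical grid and I/O

All analysis happens on a 1×1×5 mm grid (axial in-plane resolution 1 mm,
slice thickness 5 mm). Images are resampled linearly, label masks with
nearest neighbours so the label set {0, 1, 2} survives exactly. The output
grid size per axis is `round(extent / target_spacing)` — the rounding rule
matters because the 2D branch reports an *area* whose units must be stable
across studies; with 1 mm in-plane pixels the area in mm² equals the pixel
count, which is what the fusion coefficient on the area term (per mm²)
assumes. Volumes are canonicalized to LPS axis order on read; arrays are
indexed `[z, y, x]` while spacing/origin metadata is `(x, y, z)`.
A study whose resampled ROI is empty (a segmentation failure upstream) is
excluded from analysis and logged as a JSON-lines exclusion record rather
than treated as an error.

## Feature extraction

Texture features are computed on gray levels discretized with a fixed bin
width of 16 HU anchored at the region minimum
(`level = floor((v − min)/16) + 1`). Anchoring at the minimum makes every
texture feature invariant to a constant HU offset, a property the test
suite asserts. First-order features use the raw HU values. No
re-segmentation or outlier clipping is applied.

Five texture families are implemented from their defining formulas —
co-occurrence (GLCM), run length (GLRLM), size zone (GLSZM), dependence
(GLDM) and neighbouring gray-tone difference (NGTDM) — with 2D
neighbourhoods of 4 angles / 8 neighbours and 3D neighbourhoods of 13
angles / 26 neighbours. Per-angle families (GLCM, GLRLM) compute the
feature per angle and average. Every feature equals an independent
pure-loop oracle on small grids to 1e-8 in the test suite.

Degenerate conventions: GLCM correlation → 1 and IMC2 → 0 on a single gray
level; NGTDM busyness → 0 when its denominator vanishes; coarseness is
capped at 1e6; skewness → 0 for constant regions. Regions below 2 voxels
yield a flagged fallback vector instead of NaNs.

Filtered channels: a single-level undecimated `coif1` wavelet decomposition
(all sub-bands at input resolution; band letters follow array-axis order)
and a Laplacian-of-Gaussian with sigma specified in millimetres and
converted per-axis to voxel units, so anisotropic grids are smoothed
isotropically in physical space.

Feature manifests are configuration, not constants: a manifest is an
ordered list of (filter, family, feature) triples and the emitted vector
follows it deterministically. The default 3D manifest covers 4 filters ×
all families (128 features); the default 2D patch manifest keeps 41
features (all families on the original channel, first-order summaries on
the wavelet bands) because it is evaluated once per 20×20 patch — feature
*names and ordering* are the pipeline contract, not any particular count.

## 2D branch

Patches are 20×20 windows on a stride-5 lattice per axial slice, 0-based
and half-open, with a final window flush against the border when the
lattice does not reach it (edge ROI stays covered; windows are never
padded). A window is valid when strictly more than 20 of its 400 pixels
(5 %) overlap the ROI; a patch is cancerous when it contains at least one
tumor pixel. Heatmap pixels average the probabilities of every valid patch
containing the pixel. The study statistic is the largest connected region
of pixels with value strictly greater than the threshold, 8-connected
within a slice, maximum taken over slices (a 26-connected 3D mode exists
but is not the default — the area statistic is defined in-plane). The
threshold is selected on the validation cohort from the 91-point grid
0.05:0.01:0.95 by maximal AUC of the area statistic, ties resolved to the
smallest threshold.

## Classifiers and fusion

Both branches use XGBoost with logistic loss; training monitors validation
AUC and stops after 30 non-improving rounds, keeping the best-AUC
iteration. Remaining hyperparameters are library defaults (depth 6,
learning rate 0.1, ≤1000 rounds, no subsampling, single thread) recorded in
the model metadata; class reweighting is off by default with an optional
`scale_pos_weight`. Models persist as JSON with a feature-manifest hash so
schema drift is caught at predict time.

The fusion model is a maximum-likelihood logistic regression of the study
label on (p3D, area). On separable validation data the MLE diverges; the
fit then falls back to an L2-penalized estimate and flags itself
(`penalized=True`). The published coefficient triple ships as a versioned
constant so the printed equation is directly testable. Youden cutoffs are
selected over midpoints of adjacent distinct scores plus ±∞; scores equal
to a cutoff are called negative.

## Diagnostics

Proportions carry exact (Clopper–Pearson) two-sided 95 % intervals.
Likelihood-ratio intervals use the log method
(ln LR ± 1.96·√(1/a − 1/n₁ + 1/b − 1/n₀)); zero cells produce an
infinite/zero sentinel with a one-sided bound. AUCs are Mann–Whitney
statistics (ties half) with DeLong variance; the paired AUC comparison uses
the paired DeLong covariance. The trend in size-stratified sensitivity is a
Cochran–Armitage score test with equally spaced stratum scores (equivalent
to the chi-square linear-trend test); pairwise sensitivity comparisons use
exact McNemar on paired calls. The feature screen applies the two-sided
Mann–Whitney U test to continuous features and Fisher's exact test to
binary ones, with no multiplicity correction. All intervals are 95 %.

## Phantom cohorts

The generator emulates exactly the two image properties the classifiers
exploit on real contrast-enhanced CT: pancreatic tumors are *hypodense*
(lower HU than parenchyma) and *texturally busier* (stronger fine-grained
intensity variation). Each study is a 56×56×12-voxel volume at 1×1×5 mm:

* pancreas: an ellipsoid of radii ≈ 20×15×9 mm with a smoothly deformed
  boundary, filled with ~100 HU parenchyma carrying a correlated Gaussian
  field (correlation length 3 mm, sd 12 HU) plus mild fine noise (sd 3 HU);
* tumor (cases only): an ellipsoid with in-plane diameter drawn uniformly
  from 12–30 mm, intersected with the eroded pancreas so it never touches
  the boundary. Tumor voxels take a −40 HU shift and replace the smooth
  parenchymal pattern with amplified fine-grained noise (heterogeneity
  multiplier 2.0 on the high-frequency component). HU values are rounded
  to integers to mimic CT storage.

Two calibration notes. First, the minimum drawn diameter is 12 mm because
sub-centimetre lesions shift so few voxels that the integer-rounded
whole-organ median frequently ties between a case and its matched control;
at ≥12 mm the hypodensity property (case ROI median strictly below the
matched control's) holds in ≥90 % of seeded pairs, which is the contract
the generator must satisfy. Second, the "busier tumor" property is
deliberately modelled as *narrow-histogram, high-flip-rate* texture:
under fixed-bin-width discretization the gray-tone-difference busyness
statistic decreases when the histogram widens, so simply adding large
white noise makes a region *less* busy. Replacing the smooth pattern with
fine noise at ≈0.4× the bin width raises local roughness without widening
the histogram — the regime in which busyness is genuinely elevated.

The direction check compares size-matched tissue-interior windows rather
than any-portion-labeled 20×20 patches: phantom tumors are small relative
to the patch window, so labeled cancerous patches are dominated by
tumor/pancreas boundary mixtures, a regime different from cohorts whose
larger tumors contribute many interior patches.

What the phantoms do **not** emulate: abdominal anatomy and neighbouring
organs, scanner/kernel variation, contrast-phase timing, segmentation
error beyond the all-background failure case, duct dilation or atrophy
secondary to tumor. Passing the end-to-end test therefore demonstrates
that the pipeline machinery is sound and learnable signal propagates
through every stage — not that real-world accuracy is achieved.

Matched case/control pairs share the random seed (identical organ and
texture field; only the tumor modification differs), which isolates the
tumor effect for the generator's own tests.

## End-to-end experiment

The standard experiment trains on 150 phantom studies (110 model fit, 40
validation, balanced) and evaluates 100 held-out studies. Problem sizes
were chosen so the complete run — feature extraction for ~250 studies and
~50k patches, both model fits, threshold search, fusion and evaluation —
completes in a few minutes on one CPU. With the default effect sizes the
planted signal is strong: all three test AUCs reach ≈1.0, and the check on
the combined analysis is the ordering property (combined not worse than the
best single branch by more than 0.02) rather than a specific value.

## Known limitations

* The texture formulas follow the dominant open-source radiomics
  conventions but are not certified against a reference implementation;
  degenerate-case conventions differ between platforms.
* The patch-feature extractor computes one matrix per family per patch;
  very large cohorts would warrant a sliding-window reformulation.
* The penalized fallback of the fusion fit (ridge, α=1) shrinks
  coefficients strongly on separable validation sets; its output is a
  ranking-preserving score, not a calibrated probability.
* Shape features are deliberately absent: the classifiers are
  intensity/texture based, and the decision layer never sees geometry
  except through the area statistic.
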