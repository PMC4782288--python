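# Methods

`angioquant` re-implements, as a tested and reusable pipeline, the
quantitative analysis chain of a preclinical anti-angiogenic therapy
study in an orthotopic breast-cancer xenograft model: in vivo DCE-MRI
perfusion readouts, ex vivo micro-CT vascular morphometry of
contrast-cast tumors, double-stain histology quantification, HR MAS MRS
chemometrics, and a nonparametric group-comparison layer.  Because no
raw animal imaging data are deposited for such studies, every stage is
driven by a synthetic-data generator that produces phantoms with exact
ground truth; the tests quantify how faithfully each stage recovers the
designed quantities.

## DCE-MRI perfusion (`angioquant.dcemri`)

The model is purely semi-quantitative: no pharmacokinetic fitting, no
arterial input function.  For each voxel with baseline
`S0 = mean(pre-injection frames)`:

* `RSI_1min = S(t*) / S0`, with `t*` the acquired frame nearest 60 s
  post-injection.  On the default 4.8-s grid, 60 s is exactly half-way
  between frames 12 and 13 post-injection; the tie rounds **up** to
  frame 13 (62.4 s).  No temporal interpolation is performed.
* `AUC_1min` is the trapezoidal integral of the relative enhancement
  `(S − S0)/S0` over the acquired frames inside the first minute
  (12 complete 4.8-s intervals, i.e. up to 57.6 s).  Using relative
  enhancement rather than raw signal makes the AUC invariant under
  global scanner gain, so values are comparable across tumors and days.
* A voxel is *enhancing* iff `RSI_1min >= 1.5`; the boundary value is
  enhancing.  Voxels with non-positive baseline are flagged invalid and
  removed from the ROI.

Per-tumor summaries are the fraction of enhancing voxels (FEV) and the
median `AUC_1min` **over enhancing voxels only** — restricting to
enhancing voxels keeps necrotic core out of the perfusion summary; a
config switch (`median_over="roi"`) provides the all-ROI alternative.
Longitudinal changes are differences between consecutive imaging days.

## Micro-CT morphometry (`angioquant.microct`)

Input volumes are isotropic (9 μm default); anisotropic voxels raise an
error.  Segmentation is two-stage:

1. **Detection** — multi-scale Frangi vesselness (bright tubular
   structures; scales in μm, default {9, 18, 36, 72}, converted to
   Gaussian sigmas in voxels), maximum over scales rescaled to [0, 1].
   Seed voxels are the Otsu threshold of this response within the tumor
   mask.
2. **Delineation** — the final vessel mask is the union of
   Otsu-thresholded *intensity* components (26-connectivity) that
   contain at least one seed, minus components smaller than 27 voxels.

The split exists because a Hessian ridge filter is a detector, not a
delineator: on an ideal cylinder its response concentrates at the
centerline and edges and thresholding it directly misses most of the
lumen (we measured 60–180 % volume errors).  Letting the cast contrast
itself define the boundary restores volumetric accuracy, while the
vesselness seeds reject bright non-tubular blobs.  On noise-free tube
phantoms the chain recovers the rasterized vessel volume exactly.

Metrics:

* **FBV** = vessel voxels / tumor voxels.
* **Vessel caliber (VC)** is the local thickness in the
  largest-inscribed-sphere sense: the thickness at voxel p is the
  diameter of the largest sphere fully inside the mask containing p,
  where a sphere centered at c has radius equal to the exact Euclidean
  distance from c to the nearest background voxel and contains p iff
  `|p − c| < r(c)`.  The implementation iterates over the distinct
  radius values of the interior distance transform and resolves each
  coverage query with one exact distance transform, which reproduces
  brute-force sphere fitting exactly on the voxel grid (tested by
  all-voxel comparison on random masks).
* **DNV** is the exact Euclidean distance transform of the vessel-mask
  complement scaled to μm; statistics are over non-vessel tumor voxels
  only.

Summary cuts use strict inequalities: fraction of vessel voxels with
VC > 150 μm (dilated-vessel burden) and fraction of tumor voxels with
DNV > 200 μm (beyond the literature's upper oxygen-diffusion bound).
Percentiles use linear interpolation between order statistics.

## Histology quantification (`angioquant.histology`)

Fields are 8-bit RGB with a stated μm/px scale.  Stains are classified
in HSV space by fixed hue/saturation bands (one band set per study run,
recorded in the output for provenance).  Overlapping Ki67 nuclei are
split by marker-based watershed: markers are local maxima of the
interior distance transform with minimum separation half the expected
nucleus diameter (default 8 μm), flooding the negated distance
transform.

A **proliferating endothelial cell (PEC)** is a Ki67+ nucleus whose
centroid lies inside the hole-filled lectin mask; hole filling restores
the vessel pixels occluded by the overlying nucleus stain, without
which a nucleus punched into a vessel profile would never test inside.
A `rule="overlap"` alternative (≥ 50 % of nucleus pixels inside)
is available.  PEC density is count per mm² of lectin-positive area;
per-tumor pooling sums counts and areas before dividing, so density is
invariant to how fields are partitioned.

**Vessel immaturity** applies the pericyte-distance rule at the vessel
(connected-component) level: a lectin component is immature when its
minimum Euclidean distance to any α-SMA-positive pixel is ≥ 5 μm
(inclusive).  The immature fraction is immature component area over
total lectin area.  It is NaN when no lectin area exists and 1.0 when
the α-SMA mask is empty.

## Chemometrics (`angioquant.spectra`)

Preprocessing: exponential line broadening is applied as convolution
with a Lorentzian of the stated FWHM in Hz (0.3 Hz default at a 600-MHz
spectrometer frequency) — Lorentzian widths add, so this matches
time-domain exponential apodization; optional polynomial baseline
correction fits the low-intensity points; mean normalization divides
each spectrum by its mean.

PLS-DA is NIPALS PLS1 on a ±1 class response with mean-centered data,
2 latent variables by default (configurable); it is cross-checked
against scikit-learn's `PLSRegression(scale=False)` in the test suite.
The default variable set is the 3.0–3.5 ppm choline/creatine region.
Classification performance is leave-one-out sensitivity/specificity.
VIP scores use `VIP_j = sqrt(p · Σ_a w²_ja · SSY_a / Σ_a SSY_a)`; the
mean of VIP² is exactly 1.

The permutation test permutes class labels (1000 permutations by
default) with the add-one convention
`p = (#{permuted ≥ observed} + 1)/(n + 1)`, so p is never 0.  The
reported statistic is the LOO accuracy; because accuracy takes only
n + 1 discrete values, permutations are *ordered* lexicographically by
(accuracy, mean signed LOO decision margin).  Without the continuous
tie-break the null p-value distribution is conservatively clumped at
the tied accuracy levels (we measured a mean null p of 0.60); with it,
the null distribution is uniform, which is what a calibrated
permutation p should be.

## Statistics (`angioquant.stats`)

Two-tailed Mann-Whitney U tests with midrank ties.  The p-value is
exact — equivalent to full enumeration of all group assignments — when
the combined sample size is ≤ 12 and the data are tie-free (group sizes
in studies of this kind are 6–11, where exactness matters); otherwise
the normal approximation with tie and continuity correction is used.
The empirical size at α = 0.05 for 8-vs-9 groups is ≈ 0.048.
Summaries are median ± MAD with **no** 1.4826 consistency factor.
Tumor volume from calipers is `V = L·W²/2` with W ≤ L by convention
(swapped with a warning otherwise); series are normalized to the
baseline-day volume.  The PGE2 immunoassay layer fits a four-parameter
logistic curve to standards (fitted on a log-concentration axis with
positive inflection), inverts the mean of in-range replicates
(20–80 % of the response span; out-of-range replicates excluded,
samples with none usable are dropped), scales by dilution, and
normalizes to the RNA mass of the same sample.

## Synthetic phantoms (`angioquant.synthetic`)

Every generator is a pure function of its arguments including the seed.

* **Vascular phantoms** — forests of short branching random-walk tubes
  (segment length 14 voxels, branch probability 0.3, chains restarted
  after 6 segments, walks reflected at the borders), rasterized as
  unions of balls every half voxel; radii are drawn per segment from
  18–36 μm at the study scale.  Ground truth stores the exact
  rasterized mask and voxel-count FBV.  The bright/dark contrast is a
  two-level cast image plus additive Gaussian noise; partial-volume
  blur is *not* modeled, which is why noise-free recovery can be exact
  — real data would add boundary ambiguity that these tests do not
  probe.
* **DCE series** — flat baseline, then a saturating-exponential uptake
  (τ = 15 s) scaled to reach the designed peak ratio at the last frame,
  on the 200-frame / 4.8-s grid with injection after the 10th baseline
  frame; an exactly-counted voxel subset enhances.
* **Histology fields** — vessels as rotated ellipses on a jittered grid
  with clearance guarantees, so unrimmed vessels are provably ≥ 5 μm
  from any α-SMA pixel; α-SMA rims are drawn around a greedily chosen
  vessel subset matching a target unrimmed-area fraction; nuclei are
  ellipses with designed in-vessel counts and 0.6–0.9-diameter
  overlapping pairs (painted as circles so the distance transform keeps
  one maximum per nucleus).  Colors are painted strictly inside the HSV
  threshold bands and re-checked after 8-bit quantization at generation
  time.
* **Spectra** — sums of Lorentzian lines (PCho 3.23 ppm, GPC 3.24 ppm,
  plus choline, creatine, taurine, glycine neighbors), per-sample
  lognormal amplitude variability (CV 0.1), a small residual baseline
  (0.001 of the largest peak — a larger residual couples into the mean
  normalization as multiplicative noise), and additive Gaussian noise.
  Treated-class effects multiply designated peak amplitudes
  (PCho ×1.5, GPC ×0.6 by default: the direction reported for reduced
  phospholipase activity).

* **Two-arm studies** — 8 control vs 9 treated tumors imaged on days
  0/4/7 (the imaging-cohort layout), with treated-arm effects set to
  the ratios of the published group medians: FBV ×0.73, immature
  fraction ×0.71, PEC density ×0.85, day-7 enhancement amplitude ×0.6
  and enhancing fraction ×0.8 (perfusion decline between days 4 and 7);
  the spectral cohort is 6 vs 6.  The manifest (design, seeds, full
  ground truth) serializes to canonical JSON and is byte-identical when
  regenerated with the same seed.

## Problem sizes and numerical choices

Desk-scale defaults keep a full study run in tens of seconds: 48³
micro-CT volumes at 9 μm (with vesselness scales matched to the 18–36
μm phantom radii), 16×16×4 DCE ROIs over 200 frames, 384² histology
fields at 1 μm/px, 1.2-ppm spectra at 0.001 ppm resolution.  These
sizes are the package's own choice of test conditions; all thresholds
(RSI 1.5, VC 150 μm, DNV 200 μm, α-SMA 5 μm, α = 0.05) are named config
keys with the study's published values as defaults.  Degenerate inputs
(empty masks, zero baselines, zero-mean spectra, empty groups) raise
errors or return explicit NaN markers as documented per function.

## Known limitations

* The Hessian filter variant is Frangi's; the exact filter of the
  original study's citation is not recoverable, and the choice is
  isolated behind the `VesselSegmentation` interface.
* VC histograms are per-voxel distributions (the natural output of
  local thickness), not per-vessel-component.
* No motion correction, T1 mapping, pharmacokinetic modeling, stain
  deconvolution, whole-slide I/O, or peak alignment; spectra are
  assumed phased and aligned.
* Phantoms do not model scanner PSF, stain intensity gradients, or
  spectral peak shifts, so exact-recovery tests bound algorithmic
  correctness, not robustness to those real-data effects.
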