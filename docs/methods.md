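# Methods

`npabench` compares two automated segmenters of retinal capillary
nonperfusion area (NPA) on en face optical coherence tomography angiography
(OCTA): a rules-based pipeline built from image-processing primitives, and a
trainable per-pixel classifier that uses both the angiographic and the
structural channel. Because clinical OCTA datasets of this kind are not
publicly deposited, the package ships a synthetic cohort generator that
reproduces the *statistical structure* such a study depends on, so that every
stage — segmentation, agreement metrics, and cluster-aware inference — can be
exercised and validated at desk scale.

## The synthetic cohort generator

Scans are 3 × 3-mm macular en face projections on a 304 × 304 grid (pixel
pitch 3/304 ≈ 9.87 µm), one angiographic + structural image pair per
anatomical slab: superficial vascular complex (SVC), intermediate and deep
capillary plexuses (ICP, DCP), and the inner retina (union of the three).

**Vessel networks.** Each plexus is grown by iterative stochastic branching:
segments sprout from border seed points and from existing vessels toward the
points currently farthest from any vessel (a perfusion-demand map,
recomputed from the exact Euclidean distance transform), until no perfused
point lies farther than the slab's target intercapillary spacing (SVC 7 px,
ICP/DCP 5.5 px, i.e. roughly 50–70 µm half-spacing). Centerlines are dilated
to slab-specific calibers (SVC wider, plexuses near capillary width). The
networks are not anatomically faithful; only the properties the analysis
relies on are contractual — vessel-density bands (SVC ≈ 0.25–0.45),
coverage, a carved-out foveal avascular zone (FAZ; radius ~30 ± 4 px ≈
0.3 mm), and the union relation for the inner-retina slab.

**Ground-truth NPA.** The FAZ disk counts as NPA, consistent with healthy-eye
NPA means of a few tenths of mm². Disease adds extrafoveal capillary-dropout
lesions: a Gamma-distributed total area (severity-group mean: nonreferable
0.30, referable 1.40, vision-threatening 1.90 mm²) split across randomly
oriented elliptical blobs. Individual blobs are capped at ~0.5 mm² so every
blob is placeable outside the fovea; without the cap, oversized blobs are
occasionally unplaceable and the realized mean falls short of the configured
mean (the Monte-Carlo planted mean is verified to within a few percent in
tests). ETDRS level 10 (no retinopathy) always plants zero lesions. Severity
is an eye-level property held constant across visits; lesions are anatomy and
are shared across slabs and visits of an eye.

**Image formation.** The angiographic channel is flow signal (vessel mask
times an intensity field, scaled by signal strength) plus additive clipped
Gaussian decorrelation noise with standard deviation `a + b·(100 − SSI)`
(defaults a = 0.02, b = 0.003), multiplied by a slab depth factor (DCP
noisiest). The structural channel is a bright smooth reflectance field.
Shadow artifacts multiply *both* channels by an attenuation factor inside
soft-edged disks — the cue that separates artifact from true nonperfusion,
where only the angiographic signal is low. Because media opacities both cast
shadows and lower the device signal strength index (SSI), the per-visit
shadow probability rises as SSI falls (`prob·(1 + 0.03·(70 − SSI))`). SSI is
drawn per visit from severity-group-specific normals; by default the
nonreferable group scans ~8 SSI points better than the referable group,
reproducing the quality–severity confound, and the gap can be set to zero
for confound-free experiments.

**Clustering.** Cohorts follow a participants × eyes (1–2) × visits (1–3) ×
4 slabs factorial design with participant/eye/visit identifiers, the
structure the inference layer needs. Generation is a pure function of the
config including its seed.

What the generator does **not** emulate: decorrelation physics, bulk-motion
lines, projection (tail) artifacts between plexuses, vessel pulsatility,
microaneurysms, edema, or anatomically realistic plexus morphology. Passing
tests therefore demonstrate correctness of the pipeline and the claimed
statistical behaviors on data with this structure — not clinical performance
on device images.

## Rules-based segmentation

Five stages, all tunables in one `RBParams` object so sensitivity sweeps are
loops:

1. **Vesselness.** 2D Frangi tubularity response, bright-on-dark, maximum
   over scales {1, 2, 3} px (capillary-to-arteriole calibers at this pixel
   pitch), β = 0.5, c = 0.15. The structure constant c sets the response
   scale and is chosen so the three signal regimes separate: background
   noise ridges (S ≈ 0.05) score near zero, shadow-attenuated vessels
   (S ≈ 0.15–0.25) score midrange, and full-signal vessels (S ≳ 0.5)
   saturate — a smaller c saturates everything and makes the pipeline
   blind to attenuation. Implemented directly from scale-normalized
   separable Gaussian derivative filters; the discrete second-derivative
   kernel's nonzero sum is subtracted so constant images score exactly zero,
   and the construction is exactly transpose-equivariant.
2. **Reflectance-adaptive binarization.** A pixel is vessel iff its
   vesselness strictly exceeds `local_mean · m(structure) − offset`, where
   the local mean is taken over a 31-px window and
   `m = 1 − strength·(1 − structure/p99(structure))` lowers the bar where
   structural reflectance is low (signal compensation inside shadows;
   default strength 0.6). The default offset of −0.12 *raises* the threshold
   by a fixed amount and acts as a noise floor: background decorrelation
   noise produces weak spurious ridges that would otherwise litter avascular
   regions with false "vessels" and collapse the distance map.
3. **Distance map.** Exact Euclidean distance to the nearest vessel pixel
   (verified exactly against an O(N²) brute force).
4. **Calibrated threshold.** NPA = {distance > t}, with t the smallest value
   on a 1–40 px grid (0.5-px steps) such that the full pipeline yields zero
   NPA pixels outside the fovea (ground-truth FAZ dilated by 10 px) on every
   healthy calibration scan. Zero-extrafoveal-NPA is monotone in t (superlevel
   sets shrink and the cleanup stages preserve inclusion), so the search is a
   bisection. Calibration is per slab; with the default generator it lands
   around 4–5 px for the SVC and 1.5–4 px for the denser slabs.
5. **Cleanup.** Morphological opening (disk radius 1 px) and removal of
   8-connected components smaller than 0.03 mm², so small nonpathological
   intercapillary gaps are not reported.

This design reproduces the characteristic behaviors of rules-based NPA
detection: it is conservative (high precision, lower recall — every detected
region is eroded by roughly the distance threshold, and residual
false-vessel specks inside lesions hide part of them), it can report *no*
NPA at all on a scan (precision then undefined), it inflates NPA inside
shadows when reflectance compensation is weak, and on healthy eyes with
quality-linked artifacts its detected NPA correlates negatively with scan
quality — all verified as property tests.

## Learned segmentation

A fully convolutional per-pixel classifier: a fixed multiscale
Gaussian-pyramid encoder (each channel raw plus smoothed at σ ∈ {1, 2, 4, 8,
16} px) feeds per-pixel hypercolumn features to a small MLP head (24, 16
hidden units) trained with Adam on ~1500 stratified pixels per training
image. The probability map is thresholded strictly at 0.5. Because the
structural channel is in the feature stack, the model learns the
shadow/nonperfusion disambiguation; an `use_structure=False` ablation
removes it for controlled comparisons. Training is seeded and reproducible.
No deep-learning framework is used; the model is deliberately small so that
training on a few hundred images takes tens of seconds on one CPU. No claim
is made that it reproduces any particular published network — the package's
comparisons only require a trainable two-channel segmenter with calibrated
probability output.

## Agreement metrics

Pixel confusion counts honor an optional exclusion mask (artifact regions
contribute to no count). Precision is UNDEFINED when the prediction is empty,
recall when the reference is empty, IoU/F1 when both are; UNDEFINED is an
explicit value, never silently 0 or 1. Aggregation averages per-scan metrics
with UNDEFINED entries dropped and reports the effective n per metric, which
is why aggregate rows can have different counts. With these limits, an empty
prediction against a nonempty reference scores precision UNDEFINED and
recall = IoU = F1 = 0. Areas are included-pixel counts × pitch².

## Statistical inference

All estimands are ordinary full-sample statistics; all interval estimates
resample **participants** (clusters) with replacement — the cluster
bootstrap — never raw rows, because eyes of one participant and visits of
one eye are correlated. This replaces mixed-effects (random participant
intercept) estimation with a resampling scheme honoring the same dependence;
every result row records the method string, and the study manifest carries
the substitution note.

* Percentile bootstrap CIs (two-sided); bootstrap p-values by CI inversion,
  `p = 2·min(P*(θ* ≤ 0), P*(θ* ≥ 0))`, floored at 1/(B+1).
* Paired t tests on per-unit differences are classical (exact t intervals).
* Spearman's ρ uses midranks; the between-method difference of ρ against the
  same ordinal outcome bootstraps both methods jointly.
* ICC is the two-way absolute-agreement single-measurement coefficient
  ICC(A,1) from the variance-components (ANOVA) decomposition; it equals
  Pearson's r when the two methods share mean and variance and drops below
  it under systematic bias (verified against an independent implementation
  to 1e-8).
* AUROC uses the Mann–Whitney rank formulation with ties scored ½ (equal to
  the all-pairs brute force exactly, and to logistic-regression ROC for a
  single monotone predictor).
* DeLong's test compares correlated AUROCs via placement values, conditioning
  on class sizes; its null rejection rate is verified at ~5%, and its p
  agrees with a class-stratified paired-bootstrap p (the matched resampling
  scheme — unconditional resampling adds class-split variance DeLong does
  not model).
* Eye-level analyses keep each eye's first quality-passing scan; scans with
  SSI < 55 are excluded (cutoff inclusive: 55.0 is retained). Multiple
  testing is not corrected (α = 0.05, descriptive), matching the exploratory
  design.

## The study pipeline

`run_study` wires the stages: generate the analysis cohort; calibrate the
rules-based thresholds on a disjoint healthy cohort (20 eyes); train one
learned model per slab on a disjoint synthetic training cohort (50 eyes ×
4 slabs); filter; segment everything with both methods; evaluate both
against simulator ground truth on a random subset of 50 diseased eyes
(standing in for the masked manual grader — by default with zero grader
noise; an optional grader model adds boundary jitter and a small-lesion miss
rate); and assemble the report: agreement table, healthy-eye NPA-vs-SSI
correlations, NPA by severity group, Spearman correlations with ETDRS
severity, staging AUROCs with DeLong tests, between-method ICC, scatter/
waterfall (sorted differences averaged in bins of 25)/box/ROC figure data,
and a manifest with seeds, thresholds and exclusion counts. Training,
calibration and analysis cohorts are disjoint by construction (asserted on
participant identifiers).

Problem sizes: the default smoke profile uses 36 participants × 2 eyes × 1
visit (288 scans), 20 calibration eyes, 50 training eyes and 2000 bootstrap
replicates, and completes in a few minutes on one CPU; the full-inference
profile scales to 188 participants, 2 visits and 10 000 replicates. The
severity mix defaults to ~22% nonreferable / 55% referable / 23%
vision-threatening at the eye level.

## Design choices that were genuinely open

* Severity cutoffs are fixed (referable ≥ 35, vision-threatening ≥ 53 on the
  ETDRS scale); the supported level set is {10, 20, 35, 43, 47, 53, 61, 65,
  71, 75, 81, 85}.
* The FAZ is part of ground-truth NPA; the rules-based calibration targets
  only extrafoveal NPA.
* Calibration is per slab (whether the original tools calibrate globally is
  not documented anywhere we could rely on; per-slab is the conservative
  choice given the very different vessel densities).
* Reflectance compensation as threshold modulation is this package's own
  formulation, exposed as a single strength parameter and swappable.
* ICC variant, bootstrap flavor (percentile), 8-connectivity, the 0.03-mm²
  minimum region and the 31-px binarization window are package choices, each
  surfaced as a parameter.

## Known limitations

* Synthetic vessel geometry is statistical, not anatomical; absolute
  agreement numbers (e.g. IoU values) are not comparable to values measured
  on device images — only the *relative* behavior of the two methods is.
* The learned model is a hypercolumn pixel classifier, far smaller than
  clinical segmentation networks; it is an experimental instrument for the
  comparison framework, not a clinical tool.
* The grader stand-in is simulator ground truth; real manual grading has
  its own biases (the optional grader-noise model emulates only two of
  them).
* Percentile cluster-bootstrap CIs undercover slightly below ~150 clusters;
  coverage is verified at the ~300-cluster scale.
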