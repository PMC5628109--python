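# Methods

This note records the modelling and numerical choices behind `cacscore`:
what each stage computes, which constants matter, what the synthetic
phantom does and does not emulate, and where the design was genuinely open.

## Scoring pipeline

**Candidate extraction.** Candidates are maximal connected sets of voxels
with HU ≥ 130 (inclusive, so a voxel at exactly 130 falls in the first
Agatston weight band). The neighbourhood order is configurable (6, 18, 26);
the default is 26, the common clinical choice, which also keeps
motion-smeared lesions in one piece. Components of a single voxel are
removed: at attenuation-map noise levels (σ ≈ 25 HU over a ≈ 40 HU
soft-tissue background) an isolated supra-threshold voxel cannot be
distinguished from a noise excursion. No upper-size or bone-exclusion
heuristic is applied at this stage — rejecting bone and aortic calcium is
the classifier's job, keeping the extraction stage simple and lossless.

**Shape features.** Eigenvalues of the covariance of voxel positions are
computed in physical millimetres, not voxel indices; otherwise the 3 mm
slice spacing would make every flat in-plane candidate look elongated.
Ratios with a zero denominator (collinear or planar candidates) are defined
as 0.

**Intensity features.** Statistics are max, mean and SD over member voxels,
plus max and mean of Gaussian-smoothed volumes at σ ∈ {1, 2, 4} mm
(physical units, converted per axis to voxel units). The multi-scale block
measures persistence under blurring: noise specks vanish at 2–4 mm while
genuine calcium retains contrast. Both the statistic list and the scale
list are configurable; the defaults are a reasonable small family, not a
claim of uniqueness.

**Coronary-tree estimate.** A full multi-atlas segmentation needs a
library of annotated scans that cannot ship with a library package, so the
tree estimate uses a single labelled template (body-region mask, three
centerline polylines, heart centre and half-extent) mapped into the
subject by affine moment matching: the subject's body region (HU > −200)
and the template mask are summarised by centroid and second moments; the
linear part matches principal axes and per-axis scale. Principal axes are
used only when both spectra are well separated (adjacent eigenvalue gaps
above 10%); otherwise the transform falls back to per-axis scaling, since
near-degenerate eigenvectors are numerically arbitrary. Eigenvector signs
are fixed deterministically (largest-magnitude component positive).
Distance maps are exact Euclidean distance transforms (in mm) of the
rasterized centerlines, one per label plus their union, sampled at the
candidate centroid with trilinear interpolation. The phantom generator
provides a template with its true geometry; real-data use requires a
user-supplied template, and the estimate is deliberately coarse — the
features need "distance to the coronary tree" to be informative, not
anatomically exact.

**Classifier.** `sklearn` Extra-Trees with 250 trees (the canonical
published configuration of this pipeline); all other hyperparameters are
the algorithm's defaults. A candidate is labelled CAC in training when it
shares at least one voxel with the reference mask. The decision threshold
on the ensemble's CAC probability is 0.5; every reported detection metric
states the threshold through the run configuration it embeds.
Cross-validation partitions *patients*, never candidates: folds are a
seeded, deterministic, as-even-as-possible split of the sorted patient
ids, and each candidate is scored exactly once by a model that never saw
its patient.

**Quantification.** Agatston contributions are area × weight per lesion
per axial slice, with no intermediate rounding; sub-mm² pixels therefore
give fractional scores, and the risk-category boundaries are read as
half-open intervals {0}, (0, 10], (10, 100], (100, 400], (400, ∞). The
zero/positive distinction — clinically the most important one — is exact.
No slice-thickness rescaling is applied: both emulated protocols use 3 mm
slices, matching the classical score definition.

**Rank-based category matching.** Scores from different acquisition
settings are not directly comparable, but patient ranking is assumed
preserved. The reference categorization fixes a quota per category; test
patients sorted by score fill quotas from the bottom. Two rules close the
gaps the quota idea leaves open: exact-zero scores always receive the
lowest category even when that overflows its quota (a zero score cannot
indicate calcium), and a group of tied scores takes the single category
holding the majority of the group's slots (the lower category on an even
split). With many zero scores the realized lowest-category count therefore
exceeds its quota — the behaviour coarse, noisy scans actually produce.

## Agreement statistics

* Weighted κ: weights w_ij = 1 − |i−j|/(k−1) (linear) or squared
  (quadratic); the SE is the large-sample variance of weighted κ
  (Fleiss–Cohen–Everitt form) and the CI the normal interval. Published
  CIs computed by other software may differ slightly; this package labels
  its CI by method and asserts only the point estimates against published
  values. κ is undefined (flagged, not raised) when chance agreement is 1.
* Accuracy: trace/N with a Wilson score interval.
* ICC: two-way absolute-agreement, single measures, from the ANOVA mean
  squares, with the standard F-based CI. Cross-checked in the test suite
  against an independent implementation (pingouin's ICC(A,1)).
* Wilcoxon signed-rank: zero differences dropped, tied ranks averaged,
  exact null distribution up to 25 informative pairs, normal approximation
  with continuity correction above.
* κ/accuracy comparison: z = Δ/√(SE₁² + SE₂²), treating the two samples as
  independent. When both estimates come from the same patients this is
  conservative in neither direction in general; it is kept because it is
  the standard "z-score test" form, and the assumption is documented here.
* Detection metrics: a detected lesion is a true positive when it overlaps
  ≥ 1 voxel of any reference lesion. Lesion and volume sensitivity are
  per-scan values averaged over scans that have reference lesions; scans
  without reference calcium contribute only to the false-positive averages
  (count and total volume of spurious lesions), which run over all scans.

## Synthetic phantom

The phantom is parametric-geometric, built to exercise operators with
analytically known answers, not to look like a thorax. A z-invariant body
(soft tissue, 40 HU) holds two lung ellipsoids (−800 HU), an ellipsoidal
heart (blood pool 45 HU, radii ≈ 14/13/13 mm), a descending aorta and a
vertebral body (600 HU). Three labelled coronary curves (RCA/LAD/LCX) lie
on the heart surface at azimuths −75°/−15°/+45°, chosen so lesions stay
clear of the vertebra (+90°) and the aorta (≈ −164°) even after motion
blur. Lesions are uniform spheres (radius and peak HU from the cohort
ranges) on these curves; distractor calcium comprises aortic-wall plaques
and the vertebra itself.

Scenes are rendered at 4× supersampling and block-averaged onto the target
grid, so partial-volume effects arise from area weighting rather than
being painted in. Two grids are rendered per patient over a 56 mm field of
view and 12 × 3 mm slices — deliberately desk-scale; a 20-patient cohort
renders in well under a minute:

* CSCT-like: 0.35 mm in-plane, additive Gaussian noise σ = 10 HU, no blur;
* CTAC-like: 1.35 mm in-plane, noise σ = 25 HU, anisotropic Gaussian
  motion blur before downsampling, σ = 3 mm in-plane and 0.3× that through
  plane.

The blur width is the generator's model of cardiac motion during a
non-gated multi-second acquisition, which smears coronaries by several
millimetres; at 3 mm the generator reproduces the characteristic physics
of attenuation-map scoring — markedly lower scores on the coarse blurred
grid, with faint small lesions disappearing entirely — whereas much weaker
blur produces the opposite artefact (threshold "blooming", where a hot
lesion's supra-130 footprint grows on the coarse grid faster than its peak
falls). Noise is added on the target grid after downsampling, then clipped
to the scanner range [−1024, 3071] HU.

**Ground truth.** A voxel belongs to a lesion's truth mask when (a) the
noise-free (but blurred, for CTAC) rendering is ≥ 130 HU there and (b) the
lesion's own blurred volume fraction is sufficient to lift the voxel over
130 HU from the blood-pool level, i.e. fraction ≥ (130 − 45)/(peak − 45).
Condition (b) excludes supra-threshold voxels owed to nearby distractor
calcium and is provably implied by (a) in the unblurred case, so it costs
nothing there. Truth Agatston/volume scores are computed by running the
same ≥ 2-voxel connected-component rule on the truth masks as the
candidate extractor applies; a lesion whose footprint on a coarse grid is
a single voxel contributes zero to the truth score, consistent with the
extraction rule. With noise and blur disabled, the automatic end-to-end
score then equals the truth score exactly — a structural identity used as
a pipeline self-check. Cohort generation enforces a ≥ 6 mm surface gap
between lesions (more than one coarse-voxel diagonal) so distinct lesions
never share or touch voxels.

**What the phantom does not emulate** — and what passing tests therefore
do not show about real data: beam hardening, kVp-dependent HU shifts,
metal artefacts, stents, non-Gaussian reconstruction noise, true
respiratory/cardiac motion (a shift-invariant blur is a crude surrogate),
anatomical variability beyond scale/translation of a fixed geometry, and
lesions in anatomically adjacent confounders (e.g. a plaque touching the
aortic root). Classifier performance on the phantom is a correctness check
of the machinery under separable conditions, not an estimate of clinical
accuracy.

**Cohort defaults.** 1–6 lesions per patient (radius 2.0–4.5 mm, peak
220–750 HU), 1–3 aortic plaques, heart scale 0.92–1.08 with ±1.5 mm
centre jitter, and a 10% zero-calcium fraction, echoing the roughly
one-in-ten zero-score subgroup of a typical referral population. Lesion
placements are rejection-sampled against the separation rule with a
per-patient derived seed, so cohorts are reproducible bit-for-bit.

## Numerical and degenerate-input conventions

* HU values outside [−1024, 3071] are clipped on load with a warning
  rather than rejected (low-dose reconstructions overshoot routinely).
* Candidate ordering (decreasing volume, ties by first voxel in scan
  order) makes ids deterministic; all pipeline outputs are invariant to
  candidate order.
* κ undefined (chance agreement 1), ICC undefined (zero denominator) and
  Wilcoxon with no nonzero differences are reported as flags/errors, and
  the experiment report propagates the κ flag instead of failing.
* A degenerate cohort with no calcium anywhere has nothing to train on;
  the pipeline then scores every candidate as background rather than
  crashing inside the classifier.
* Cross-validation seeds each fold's ensemble with `seed + fold` so fold
  models are independent but reproducible.

## Problem sizes used in the checks

The acceptance script and test suite run the full pipeline on a 20-patient
default cohort (tenfold cross-validation) and a 6-patient noise-free
cohort (threefold), sizes chosen so the whole suite completes in a few
minutes on one CPU while every patient still contributes multiple
candidates of both classes. The published-table statistics are exact
computations on 128-patient integer tables and involve no simulation.
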