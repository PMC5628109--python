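# cacscore

Automatic coronary artery calcium (CAC) scoring and cardiovascular risk
categorization for non-gated CT attenuation-correction (CTAC) volumes.

Every cardiac PET/CT or SPECT/CT exam already contains a low-dose CT
acquired to correct the emission data for attenuation. Those maps are
noisy, coarse (≈1.35 mm in-plane, 3 mm slices) and blurred by cardiac
motion, so they are never used for calcium scoring in routine practice —
that is done on a separate, ECG-triggered calcium-scoring CT (CSCT).
`cacscore` implements the machine-learning pipeline that scores CAC
directly on the attenuation map, so cardiovascular risk can be read off a
scan the patient already received, plus the agreement statistics needed to
compare scoring methods, and a synthetic phantom generator that makes the
whole pipeline testable without clinical data.

Intended users: researchers in cardiac image analysis and nuclear
cardiology who want a transparent, scriptable reference implementation of
threshold-based calcium quantification and of the surrounding evaluation
machinery.

## Method

The pipeline mirrors standard clinical calcium scoring with a learned
lesion classifier in the middle:

1. **Candidate extraction** — voxels with attenuation ≥ 130 HU are grouped
   by 3D connected-component labelling (26-neighbourhood by default);
   single-voxel components are discarded as indistinguishable from noise.
2. **Features** — each candidate is described by its volume; shape ratios
   λ₂/λ₁, λ₃/λ₁, λ₃/λ₂ of the PCA eigenvalues of its voxel coordinates (in
   mm); intensity statistics (max, mean, SD) of the raw volume and of
   Gaussian-smoothed copies at σ ∈ {1, 2, 4} mm; and location: distances to
   the RCA/LAD/LCX centerlines of a template-based coronary-tree estimate,
   plus heart-centred normalized coordinates. The tree estimate maps a
   labelled template into the subject by affine moment matching (centroid,
   principal axes, per-axis scale of the body region).
3. **Classification** — an ensemble of 250 extremely randomized trees
   (Extra-Trees) separates true CAC from aortic calcifications, bone and
   noise. Evaluation uses tenfold cross-validation with strict per-patient
   separation of training and test data.
4. **Quantification** — the accepted lesions receive the Agatston score

   *A* = Σ_lesions Σ_slices (area mm²) × *w*,  *w* = 1, 2, 3, 4 for slice
   peak HU in [130, 200), [200, 300), [300, 400), ≥ 400,

   a volume score (mm³), and one of five risk categories: score 0, (0, 10],
   (10, 100], (100, 400], > 400.
5. **Agreement statistics** — linearly weighted Cohen's κ with
   large-sample SE and CI, accuracy with Wilson CI, two-way
   absolute-agreement ICC, Wilcoxon signed-rank (exact for ≤ 25 pairs),
   z-comparison of κ/accuracy pairs, per-scan detection sensitivity and
   false-positive burden, and the rank-based category matching used to
   compare scores across scanner settings.

## Worked example

```python
import cacscore as cs

# synthesize one patient: paired calcium-scoring CT and attenuation map
spec = cs.PhantomSpec(
    lesions=(
        cs.LesionSpec("LAD", 0.30, 4.5, 700.0),
        cs.LesionSpec("RCA", 0.70, 4.0, 600.0),
    ),
    aortic_calcs=(cs.AorticCalcSpec(0.5, 2.5, 450.0),),
    seed=3,
)
csct, ctac, truth = cs.generate_pair(spec)
print("truth Agatston  CSCT:", round(truth.agatston["CSCT"], 2),
      " CTAC:", round(truth.agatston["CTAC"], 2))

# candidate extraction + features on the noisy attenuation map
candidates = cs.extract_candidates(ctac, threshold=130.0)
tree = cs.estimate_coronary_tree(ctac, cs.make_template())
features = cs.featurize(candidates, ctac, tree)
print("candidates:", len(candidates),
      " nearest-centerline distances (mm):",
      [round(d, 1) for d in features["loc_dist_union_mm"]])
```

prints

```
truth Agatston  CSCT: 1070.77  CTAC: 821.95
candidates: 3  nearest-centerline distances (mm): [12.2, 1.2, 2.0]
```

The same anatomy scores lower on the attenuation map (821.95 vs 1070.77):
partial volume and motion blur push rim voxels below the 130 HU threshold.
Three candidates are extracted from the CTAC scan; the two true lesions sit
1–2 mm from the estimated coronary tree while the vertebral bone candidate
is 12 mm away — the separation the classifier exploits.

Agreement statistics work directly on confusion tables. On the bundled
128-patient cross-table of manual vs automatic risk categories in rest
attenuation maps:

```python
from cacscore.datasets import example_confusion
m = example_confusion("ctac_rest_manual_vs_auto")
res = cs.weighted_kappa(m, "linear")
print(f"kappa {res.kappa:.2f} (95% CI {res.kappa_ci95[0]:.2f}-{res.kappa_ci95[1]:.2f}),"
      f" accuracy {cs.accuracy(m).accuracy:.1%}")
# kappa 0.85 (95% CI 0.78-0.91), accuracy 82.8%
```

A `cacscore` command-line tool exposes each stage (`simulate`, `extract`,
`featurize`, `train`, `predict`, `crossval`, `score`, `agree`, `run`); see
`cacscore --help`.

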