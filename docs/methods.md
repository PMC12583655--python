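# Methods notes

## Model and assumptions

Regional pathology is quantified as a w-score: the residual of an observed
measure from a healthy-control (HC) expectation, scaled by the HC residual
SD. The expectation is an OLS fit of the measure on age, sex, MRI field
strength and estimated total intracranial volume (eTIV), with raw-scale
(unstandardized) coefficients. Assumptions inherited from this model
class:

- linearity of each covariate effect (notably age; see Limitations),
- homoscedastic Gaussian residuals per (region, measure),
- the HC pool defines normality; disease groups are never used in fitting.

Covariate encodings: sex female = 0 / male = 1; field strength 1.5 T = 0 /
3 T = 1 (other field strengths are rejected — the covariate is binary by
design since the modeled scanner fleet is 1.5/3 T). Any affine recoding of
a binary covariate leaves w-scores unchanged (tested). eTIV enters as a
raw covariate in mm³; volumes are not proportionally pre-scaled.

`residual_sd` uses the sample SD of HC residuals with ddof = 1 rather than
the regression standard error with ddof = n − p. The choice is isolated in
`fit_normative` and makes in-sample HC w-scores have exactly unit sample
SD (ddof = 1), which the suite asserts to 1e-10. With HC n in the
hundreds the two differ by < 1%.

## Hierarchy and aggregation

The bundled atlas (`src/neuroprofile/data/atlas_dkt.yaml`) has 100 leaves
— 31 DKT cortical parcels per hemisphere, 8 subcortical gray structures
per hemisphere, cerebral white matter (L/R + hypointensities + 5 corpus
callosum segments), 9 ventricular/CSF structures, 4 cerebellar structures,
brainstem — under 24 parent concepts. The grouping follows standard
neuroanatomical abstractions (lobes, hemispheres, cerebrum, ventricular
system, cerebellum, whole brain) and is data, not code: swapping the YAML
adapts the pipeline to another atlas. The file fixes child order
(anatomical order), which the sunburst layout relies on.

Aggregation: parent volume = sum of child volumes; parent thickness =
surface-area-weighted mean of cortical leaf descendants (unweighted mean
when areas are absent) — the standard "mean cortical thickness"
convention. Parent models are fit directly on the aggregated measures.
For volume, OLS linearity makes this equivalent to summing the child
coefficient vectors on the shared HC design matrix; the suite checks this
additivity to 1e-8 (absolute) for every parent. For thickness, where
summation is not meaningful, direct fitting is the definition.

Ventricular regions use the same w-score; their pathological direction is
positive (enlargement). No sign flip exists in the engine — direction
semantics live in the color scale of the report layer.

## Similarity and evaluation

Profile vectors concatenate volume w-scores over all 124 nodes and
thickness w-scores over the 76 thickness-supporting nodes (canonical
atlas order, volume block first). Cosine similarity is magnitude-
invariant, so DSimI = cos(x, mean_AD) − cos(x, mean_bvFTD) responds to
*which* regions deviate together, not how severely. Classification
thresholds DSimI at exactly 0 (never tuned); an exact zero classifies as
bvFTD — a deterministic tie rule for a measure-zero event.

Evaluation: stratified 10-fold cross-validation (stratification keeps the
minority bvFTD class in every fold; folds are seeded and shared across
subset ablations for comparability). Group means are recomputed from
training subjects only — a leakage probe in the suite verifies that
perturbing a test subject cannot move its fold's training means.
Sensitivity, specificity and F1 take bvFTD (the minority class) as
positive; ROC-AUC uses the tie-corrected Mann-Whitney formulation, which
an O(n²) pairwise-concordance oracle reproduces exactly in tests.
Anatomical subsets expand named seed nodes to both hemispheres plus all
descendants; "Cerebrum" excludes cerebellum, brainstem and ventricles;
"Whole Brain" is all 124 nodes. Normative models are fit once on HC
(who are not part of the AD/bvFTD sample) and not refit per fold.

## Sunburst reports

Geometry is value-independent: every leaf spans 360°/100, parents span
the contiguous union of their leaves, and right-lateralized subtrees are
traversed in reverse order so homologous lobes face each other. Two
subjects therefore differ only in colors and hover text (asserted in
tests). Color semantics: |w| ≤ 1.5 is the clinically "normal" band and
renders the neutral yellow; beyond 1.5 a single linear ramp runs to the
saturated hue (red for w < 0, green for w > 0), clamping at the
saturation cap. Defaults: cap 4.0 w-units (keeps severe single-subject
scores distinguishable without unbounded scaling), anchors #f7e967 /
#b2182b / #1a9850, interpolated linearly in RGB. The ramp is continuous
at the band edge and strictly monotone in |w|; the 2.0 "significant"
threshold is annotated in the legend rather than introducing a second
ramp segment — the minimal mapping satisfying both the normal-band and
intensification semantics. Measure fusion for display uses the maximum-
absolute-value operator per region, sign preserved. The renderer writes
self-contained HTML (inline SVG + small vanilla JS for drill-down) plus a
JSON sidecar holding the exact spec for programmatic comparison.

## Synthetic cohorts

The generator draws covariates per diagnosis (age, sex and group sizes'
imbalance follow the source cohorts' demographics: HC 70.4 ± 7.6 y / 56.7%
female, MCI 72.5 ± 7.4 / 44.5%, AD 74.1 ± 7.7 / 51.1%, bvFTD 62.8 ± 8.2 /
35.4%; 70% 3 T; eTIV ~ N(1.45e6, 1.4e5) mm³) and then generates each leaf
measure from ground-truth linear coefficients plus a diagnosis effect δ
(in residual-SD units) plus noise. Default group sizes (HC 400, MCI 150,
AD 150, bvFTD 60) scale the source cohorts down by roughly 4× while
keeping the ~2.5:1 AD:bvFTD imbalance; every test and example states its
sizes explicitly.

Noise is ε_i = σ_i(ρ·g + √(1−ρ²)·e_i) with one shared standard-normal g
per subject and ρ = 0.95. The shared factor models the strong
inter-regional correlation of residual brain volume around a covariate
expectation (global brain reserve / global atrophy). It is also what
makes aggregation coherent: a uniform δ over a parent's k children
reappears at the parent as δ·k/√(ρ²k² + (1−ρ²)k) ≈ δ/ρ; with fully
independent noise the parent mean w would instead inflate toward δ·√k.
Marginal per-region residual SD is exactly σ_i either way.

Effect maps are qualitative design choices, not fitted values: AD =
uniform −2.0 over temporal cortical leaves (volume and thickness),
hippocampus −2.5 / amygdala −2.0, inferior lateral ventricles +2.0, mild
parietal spread −0.8; bvFTD = frontal −2.5 plus temporal −2.0 and
medial-temporal involvement; MCI = medial-temporal restriction of the AD
map × 0.4. An optional `nonlinear_age` switch adds a mild concave age
effect (off by default) to emulate the known failure mode of linear age
models in younger patients.

What the generator does **not** emulate: site/cohort batch effects beyond
the field-strength covariate, segmentation error, longitudinal change,
non-Gaussian residuals, and disease heterogeneity (every AD subject
shares one effect map up to noise). Passing tests therefore demonstrate
that the pipeline recovers what its model class assumes — calibration,
effect recovery, pattern separability — not clinical performance on real
cohorts; the perfect whole-brain AUC on default synthetic data reflects
the clean, homogeneous effect maps, and real-data AUCs are expected to be
substantially lower.

## Numerical and interface choices

- OLS via `numpy.linalg.lstsq`; degenerate designs (constant covariate,
  rank deficiency) raise with the offending covariate named.
- Cosine is clipped to [−1, 1] against rounding; zero vectors and empty
  shared key sets are errors, not NaNs.
- Problem sizes in tests: shared fixture cohort HC 120 / AD 40 / bvFTD 25;
  recovery checks use HC 500 / AD 100; the classification check uses the
  default HC 400 / AD 150 / bvFTD 60. All seeds are fixed in the tests.
- OWL vocabulary: `rdfs:subClassOf` for anatomical containment (a class
  tree, not a partonomy — the rendered hierarchy is a subsumption tree),
  custom annotation properties in the package namespace for segmentation
  IDs, layout order, coefficients and residual SDs; subject measurements
  serialize as class instances with data properties. Round trips
  (structure, annotations, coefficients; RDF/XML and Turtle) are lossless
  and re-validated on load.
- Stats-file ingestion reads `GrayVol` as the cortical volume and
  `ThickAvg`/`SurfArea` from the aparc-DKT dialect; unmapped structures
  warn and are ignored, missing atlas leaves are errors.

## Known limitations

- Linear age modeling overestimates deviations for subjects far from the
  HC age center (relevant for bvFTD, mean age ~63 vs HC ~70).
- No mixed-effects, spline/GP normative models, and no ComBat-style site
  harmonization.
- The 24-parent grouping is one defensible reconstruction of standard
  neuroanatomical abstractions; alternative lobe assignments (e.g.
  paracentral in parietal rather than frontal) are equally defensible and
  swappable via the atlas file.
- The DSimI is a two-class index; it does not abstain and has no
  calibrated probability interpretation.
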