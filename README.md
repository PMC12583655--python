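# neuroprofile

Ontology-based quantification and reporting of regional brain-MRI
pathology, with cosine-similarity differential diagnosis of Alzheimer's
disease (AD) versus behavioral-variant frontotemporal dementia (bvFTD).

The package is aimed at neuroimaging researchers who already have
region-level segmentation output (DKT-protocol volumes in mm³, cortical
thickness in mm, eTIV) — e.g. from FastSurfer/FreeSurfer `stats` files —
and want covariate-adjusted deviation scores, hierarchical summaries, and
a pattern-based differential-diagnosis index, without access to raw images.

## Method

**w-scores.** For every region of interest (ROI) *r* and measure
*y* ∈ {volume, thickness}, an ordinary-least-squares model is fit on
healthy controls (HC) only:

    y ~ β0 + β1·age + β2·sex + β3·field_strength + β4·eTIV

and a subject's deviation is the covariate-adjusted z-score

    W = (y − ŷ) / SD(e_controls)

with SD(e_controls) the sample SD (ddof = 1) of the HC residuals.
Negative W = atrophy; positive W = enlargement (ventricles).

**Hierarchy.** The 100 leaf ROIs of the bundled DKT-style atlas are
aggregated under 24 parent concepts (lobes, hemispheres, cerebrum,
ventricular system, cerebellum, whole brain). Parent volume is the sum of
child volumes; parent thickness is the surface-area-weighted mean over
cortical descendants. Parents get their own normative models and
w-scores, and for volume the parent coefficients provably equal the sum
of the child coefficients (an additivity property the test suite checks
to 1e-8). The hierarchy, model coefficients and subject scores can be
persisted as an OWL 2 ontology (RDF/XML or Turtle).

**Disease Similarity Index.** A subject's profile x (w-scores over all
ROIs, parents and leaves, volume and thickness) is compared with the AD
and bvFTD group-mean profiles by cosine similarity:

    DSimI(x) = cos(x, w̄_AD) − cos(x, w̄_bvFTD)

DSimI ∈ [−2, 2]; thresholded at 0 it yields the differential call
(positive → AD). Evaluation uses stratified 10-fold cross-validation with
group means refit per training fold, reported as ROC-AUC and balanced
accuracy over anatomical subsets (amygdala → whole brain).

**Sunburst reports.** A profile renders as a self-contained interactive
HTML sunburst: whole brain at the center, leaves outermost, fixed
value-independent layout with mirrored hemispheres, and a diverging color
scale (yellow inside |w| ≤ 1.5, ramping to saturated red for atrophy and
green for enlargement, clamped at |w| = 4).

**Synthetic cohorts.** Because the clinical source cohorts are
restricted-access, `neuroprofile.synthetic` generates cohorts from the
same model class with known ground truth (coefficients, residual SDs,
per-diagnosis effect maps), matching the source demographics (e.g. AD age
74.1 ± 7.7 y, bvFTD 62.8 ± 8.2 y).

## Worked example

```python
import neuroprofile as npf

atlas = npf.load_default_atlas()                     # 100 leaves, 24 parents
cfg = npf.default_config(atlas, n={"MCI": 0}, seed=7)
cohort, truth = npf.generate_cohort(cfg, atlas)      # HC=400, AD=150, bvFTD=60
models = npf.fit_normative(cohort.subset("HC"), atlas)

dx = [r for r in cohort.records if r.diagnosis in ("AD", "bvFTD")]
profiles = [npf.compute_wscore_profile(r, models, atlas) for r in dx]
labels = [r.diagnosis for r in dx]
print(npf.subset_evaluation(profiles, labels, atlas, k=10, seed=7).round(3))
```

prints the ablation table

```
                   subset  n_regions  auc_mean  auc_sd  balanced_accuracy_mean  balanced_accuracy_sd
                 Amygdala          2     0.423   0.098                   0.440                 0.091
              Hippocampus          2     0.536   0.139                   0.480                 0.114
            Temporal Lobe         16     0.474   0.084                   0.463                 0.149
             Frontal Lobe         22     0.806   0.088                   0.720                 0.050
Frontal and Temporal Lobe         38     1.000   0.000                   1.000                 0.000
                 Cerebrum        103     1.000   0.000                   1.000                 0.000
              Whole Brain        124     1.000   0.000                   1.000                 0.000
```

Reading it: focal medial-temporal structures alone carry almost no
AD-vs-bvFTD signal under the default effect maps (both diseases atrophy
them similarly, AUC ≈ 0.5); the frontal lobe — affected in bvFTD but not
AD — separates well on its own (AUC 0.81); combining frontal and temporal
lobes, or any superset, separates the synthetic groups completely. On the
same cohort, group statistics at the left frontal lobe
(`npf.group_stats(profiles, labels, "lh_frontal_lobe")`) give Welch's
t = 17.3 (df ≈ 93.7) and Cohen's d = 2.8 — the frontal w-score gap that
drives the classification.

The same pipeline is scriptable from the shell:

```bash
neuroprofile simulate --seed 5 --out cohort.csv
neuroprofile fit --hc-table cohort.csv --out models.owl
neuroprofile score --table cohort.csv --models models.owl --out profiles.csv
neuroprofile evaluate --profiles profiles.csv --labels labels.csv --out metrics.csv
neuroprofile report --profile profiles.csv --out report.html
```

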