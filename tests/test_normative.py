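"""Normative engine: aggregation, OLS fitting, w-score properties."""

import numpy as np
import pytest

import neuroprofile as npf
from neuroprofile.io import Cohort, SubjectRecord
from neuroprofile.normative import (CovariateVector, NormativeError,
                                    NormativeModel, aggregate_to_parents,
                                    design_matrix)


def _mini_record(volumes, thicknesses=None, areas=None):
    return SubjectRecord(subject_id="m1", diagnosis="HC", age=70.0,
                         sex="female", field_strength=3.0, etiv=1.5e6,
                         volumes=volumes, thicknesses=thicknesses or {},
                         areas=areas or {})


def test_parent_volume_is_child_sum(mini_atlas):
    rec = _mini_record({"a": 100.0, "b": 200.0}, {"a": 2.0, "b": 3.0})
    volumes, _ = aggregate_to_parents(rec, mini_atlas)
    assert volumes["root"] == 300.0
    assert volumes["a"] == 100.0 and volumes["b"] == 200.0


def test_parent_thickness_area_weighted(mini_atlas):
    rec = _mini_record({"a": 1.0, "b": 1.0}, {"a": 2.0, "b": 3.0},
                       {"a": 10.0, "b": 30.0})
    _, thick = aggregate_to_parents(rec, mini_atlas)
    assert thick["root"] == pytest.approx(2.75)   # (2*10 + 3*30)/40
    rec_no_area = _mini_record({"a": 1.0, "b": 1.0}, {"a": 2.0, "b": 3.0})
    _, thick = aggregate_to_parents(rec_no_area, mini_atlas)
    assert thick["root"] == pytest.approx(2.5)    # unweighted fallback


def test_root_volume_telescopes(atlas, small_cohort):
    cohort, _ = small_cohort
    volumes, _ = aggregate_to_parents(cohort.records[0], atlas)
    assert volumes[atlas.root_id] == pytest.approx(
        sum(cohort.records[0].volumes.values()))


def test_w_score_hand_example():
    model = NormativeModel("r", "volume",
                           np.array([1000.0, -5.0, 0.0, 0.0, 0.0]),
                           residual_sd=50.0, n_train=100)
    cov = CovariateVector(age=70.0, sex_code=0.0, field_code=0.0,
                          etiv=1.4e6)
    assert npf.w_score(675.0, model, cov) == pytest.approx(0.5)
    assert npf.w_score(model.predict(cov), model, cov) == 0.0
    y = model.predict(cov) - 2 * model.residual_sd
    assert npf.w_score(y, model, cov) == pytest.approx(-2.0)


def test_w_score_monotone_decreasing_in_y():
    model = NormativeModel("r", "volume",
                           np.array([10.0, 0.0, 0.0, 0.0, 0.0]), 2.0, 50)
    cov = CovariateVector(60.0, 1.0, 1.0, 1.4e6)
    ws = [npf.w_score(y, model, cov) for y in (12.0, 10.0, 8.0)]
    assert ws[0] > ws[1] > ws[2]


def test_fit_recovers_generator_coefficients(atlas):
    """Near-noiseless synthetic HC: OLS must recover the true coefficients."""
    cfg = npf.default_config(atlas, n={"HC": 300, "MCI": 0, "AD": 0,
                                       "bvFTD": 0}, seed=5)
    truth = cfg.truth
    for key in truth.residual_sd:
        truth.residual_sd[key] = 1e-6 if key[1] == "thickness" \
            else truth.residual_sd[key] * 1e-8
    cohort, _ = npf.generate_cohort(cfg, atlas)
    models = npf.fit_normative(cohort, atlas)
    for rid in ("left_hippocampus", "lh_superiorfrontal", "brainstem"):
        got = models[(rid, "volume")].coefficients
        want = truth.coefficients[(rid, "volume")]
        assert np.allclose(got, want, rtol=1e-6, atol=1e-6 * abs(want[0]))


def test_in_sample_hc_scores_standardized(atlas, small_cohort, hc_models,
                                          scored):
    cohort, _ = small_cohort
    profiles, labels = scored
    hc = [p for p, l in zip(profiles, labels) if l == "HC"]
    for key in [("left_hippocampus", "volume"), (atlas.root_id, "volume"),
                ("lh_temporal_lobe", "thickness")]:
        w = np.array([p.scores[key] for p in hc])
        assert abs(w.mean()) < 1e-10
        assert w.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_row_order_does_not_change_models(atlas, small_cohort):
    cohort, _ = small_cohort
    hc = cohort.subset("HC")
    flipped = Cohort(hc.records[::-1])
    a = npf.fit_normative(hc, atlas)
    b = npf.fit_normative(flipped, atlas)
    for key in a.models:
        assert np.allclose(a[key].coefficients, b[key].coefficients,
                           rtol=1e-9)


def test_sex_recoding_leaves_w_scores_unchanged(atlas, small_cohort):
    """Any two-level sex coding yields identical w-scores."""
    cohort, _ = small_cohort
    hc = cohort.subset("HC")
    models = npf.fit_normative(hc, atlas)
    target = cohort.records[-1]
    base = npf.compute_wscore_profile(target, models, atlas)

    from neuroprofile import io as io_mod
    old = dict(io_mod.SEX_CODE)
    try:
        io_mod.SEX_CODE.update({"female": 5.0, "male": -3.0})
        models2 = npf.fit_normative(hc, atlas)
        alt = npf.compute_wscore_profile(target, models2, atlas)
    finally:
        io_mod.SEX_CODE.update(old)
    for key in base.scores:
        assert base.scores[key] == pytest.approx(alt.scores[key],
                                                 abs=1e-8)


def test_unit_rescaling_invariance(atlas, small_cohort, hc_models):
    """Rescaling a measure's units rescales the model, not the w-score."""
    cohort, _ = small_cohort
    rec = cohort.records[0]
    cov = CovariateVector.from_record(rec)
    model = hc_models[("left_hippocampus", "volume")]
    scaled = NormativeModel("left_hippocampus", "volume",
                            model.coefficients * 1000.0,
                            model.residual_sd * 1000.0, model.n_train)
    y = rec.volumes["left_hippocampus"]
    assert npf.w_score(y, model, cov) == pytest.approx(
        npf.w_score(y * 1000.0, scaled, cov), rel=1e-12)


def test_profile_covers_all_nodes(atlas, scored):
    profiles, _ = scored
    vol_keys = [k for k in profiles[0].scores if k[1] == "volume"]
    thick_keys = [k for k in profiles[0].scores if k[1] == "thickness"]
    assert len(vol_keys) == 124
    assert len(thick_keys) == len(atlas.thickness_ids())
    assert all(np.isfinite(list(profiles[0].scores.values())))


def test_group_mean_profile(scored):
    profiles, labels = scored
    gp = npf.group_mean_profile(profiles, "HC", labels)
    assert gp.n == labels.count("HC")
    for key in [("cerebrum", "volume"), ("rh_frontal_lobe", "thickness")]:
        assert abs(gp.mean_scores[key]) < 1e-10   # in-sample OLS property
    single = npf.group_mean_profile([profiles[0]], "solo")
    assert single.mean_scores == pytest.approx(profiles[0].scores)


def test_fit_rejects_bad_cohorts(atlas, small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(NormativeError, match="HC only"):
        npf.fit_normative(cohort, atlas)
    single_sex = Cohort([r for r in cohort.subset("HC").records
                         if r.sex == "female"][:30])
    with pytest.raises(NormativeError, match="sex"):
        npf.fit_normative(single_sex, atlas)


def test_design_matrix_layout(small_cohort):
    cohort, _ = small_cohort
    X = design_matrix(cohort.records[:3])
    assert X.shape == (3, 5)
    assert np.all(X[:, 0] == 1.0)
    assert np.all(X[:, 4] > 1e5)       # eTIV in mm^3, raw covariate
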