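"""Cosine similarity, DSimI, classification, and its evaluation loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import neuroprofile as npf
from neuroprofile.similarity import (ProfileVector, RegionSubset,
                                     SimilarityError, table_subsets)

from conftest import brute_force_auc


def _vec(values, prefix="r"):
    keys = tuple((f"{prefix}{i}", "volume") for i in range(len(values)))
    return ProfileVector(keys, np.asarray(values, dtype=float))


class TestCosine:
    def test_basic_geometry(self):
        x = _vec([1.0, 2.0, -3.0])
        assert npf.cosine(x, x) == pytest.approx(1.0)
        assert npf.cosine(x, _vec([-1.0, -2.0, 3.0])) == pytest.approx(-1.0)
        assert npf.cosine(_vec([1.0, 0.0]), _vec([0.0, 1.0])) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(SimilarityError, match="zero"):
            npf.cosine(_vec([0.0, 0.0]), _vec([1.0, 1.0]))

    def test_disjoint_keys_rejected(self):
        with pytest.raises(SimilarityError, match="share"):
            npf.cosine(_vec([1.0], "a"), _vec([1.0], "b"))

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, c):
        x = _vec([1.0, -2.0, 0.5, 4.0])
        y = _vec([0.3, -1.0, 2.0, -0.2])
        scaled = ProfileVector(y.keys, y.values * c)
        assert npf.cosine(x, scaled) == pytest.approx(npf.cosine(x, y),
                                                      rel=1e-9)


class TestDSimI:
    def test_worked_example(self):
        """Printed single-subject cosines 0.47 (AD) and 0.29 (bvFTD)."""
        d = npf.dsimi_from_cosines(0.47, 0.29)
        assert d == pytest.approx(0.18, abs=1e-12)
        assert npf.classify(d) == "AD"

    def test_antisymmetry_and_bounds(self):
        x, a, b = _vec([1.0, 2.0]), _vec([2.0, 1.0]), _vec([-1.0, 1.0])
        assert npf.dsimi(x, a, b) == pytest.approx(-npf.dsimi(x, b, a))
        assert -2.0 <= npf.dsimi(x, a, b) <= 2.0

    def test_tie_and_sign_rules(self):
        assert npf.classify(0.18) == "AD"
        assert npf.classify(-0.5) == "bvFTD"
        assert npf.classify(0.0) == "bvFTD"          # documented tie rule

    def test_dsimi_scale_invariance_of_inputs(self):
        x, a, b = _vec([1.0, -2.0, 3.0]), _vec([1.0, 1.0, 1.0]), \
            _vec([2.0, -1.0, 0.0])
        big = ProfileVector(x.keys, x.values * 137.0)
        assert npf.dsimi(big, a, b) == pytest.approx(npf.dsimi(x, a, b),
                                                     rel=1e-9)


class TestProfileVector:
    def test_whole_brain_length(self, atlas, scored):
        profiles, _ = scored
        v = npf.profile_vector(profiles[0], atlas)
        assert len(v) == 124 + len(atlas.thickness_ids())
        volume_part = [k for k in v.keys if k[1] == "volume"]
        assert volume_part == list(v.keys[:124])     # volume block first

    def test_leaf_pair_subset(self, atlas, scored):
        profiles, _ = scored
        subset = RegionSubset("hip", ["left_hippocampus"])
        v = npf.profile_vector(profiles[0], atlas, subset,
                               measures=("volume",))
        assert len(v) == 2       # contralateral mate auto-included

    def test_deterministic_ordering(self, atlas, scored):
        profiles, _ = scored
        a = npf.profile_vector(profiles[0], atlas)
        b = npf.profile_vector(profiles[0], atlas)
        assert a.keys == b.keys and np.array_equal(a.values, b.values)

    def test_subset_expansion_bilateral(self, atlas):
        sub = RegionSubset("Temporal Lobe", ["lh_temporal_lobe"])
        expanded = sub.expand(atlas)
        assert "rh_temporal_lobe" in expanded
        assert "lh_middletemporal" in expanded and \
            "rh_middletemporal" in expanded


class TestRocAuc:
    def test_extremes(self):
        assert npf.roc_auc([1, 2, 3, 10, 11, 12],
                           ["b", "b", "b", "a", "a", "a"],
                           positive="a") == 1.0
        with pytest.raises(SimilarityError):
            npf.roc_auc([1, 2], ["a", "a"], positive="a")

    def test_matches_brute_force_concordance(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.choice([-1.0, 0.0, 0.5, 1.5, 2.0], size=n) \
                + rng.normal(0, 1, n).round(1)
            labels = rng.choice(["AD", "bvFTD"], size=n)
            if len(set(labels)) < 2:
                continue
            assert npf.roc_auc(scores, labels, "AD") == pytest.approx(
                brute_force_auc(scores, labels, "AD"), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=30)
        y = rng.choice(["AD", "bvFTD"], size=30)
        assert npf.roc_auc(np.exp(s), y, "AD") == pytest.approx(
            npf.roc_auc(s, y, "AD"))


class TestCrossValidation:
    def test_separable_construction(self, atlas, scored):
        profiles, labels = scored
        dx = [(p, l) for p, l in zip(profiles, labels)
              if l in ("AD", "bvFTD")]
        cv = npf.cross_validate([p for p, _ in dx], [l for _, l in dx],
                                atlas, k=5, seed=4)
        assert cv.mean("auc") >= 0.9
        for m in cv.metrics.columns:
            assert ((cv.metrics[m] >= 0) & (cv.metrics[m] <= 1)).all()

    def test_seed_reproducibility(self, atlas, scored):
        profiles, labels = scored
        dx = [(p, l) for p, l in zip(profiles, labels)
              if l in ("AD", "bvFTD")]
        args = ([p for p, _ in dx], [l for _, l in dx], atlas)
        a = npf.cross_validate(*args, k=5, seed=9)
        b = npf.cross_validate(*args, k=5, seed=9)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.metrics.equals(b.metrics)

    def test_no_test_leakage_into_training_means(self, atlas, scored):
        """Perturbing a test subject must not move that fold's means."""
        profiles, labels = scored
        dx = [(p, l) for p, l in zip(profiles, labels)
              if l in ("AD", "bvFTD")]
        ps, ls = [p for p, _ in dx], [l for _, l in dx]
        base = npf.cross_validate(ps, ls, atlas, k=5, seed=2)
        victim = 0
        fold = int(base.fold_assignment[victim])
        perturbed = npf.WScoreProfile(
            ps[victim].subject_id,
            {k: w + 37.0 for k, w in ps[victim].scores.items()})
        ps2 = [perturbed if i == victim else p for i, p in enumerate(ps)]
        again = npf.cross_validate(ps2, ls, atlas, k=5, seed=2)
        for cls in ("AD", "bvFTD"):
            assert base.train_means[fold][cls] == pytest.approx(
                again.train_means[fold][cls])

    def test_small_class_raises(self, atlas, scored):
        profiles, labels = scored
        dx = [(p, l) for p, l in zip(profiles, labels)
              if l in ("AD", "bvFTD")]
        with pytest.raises(SimilarityError, match="smaller k"):
            npf.cross_validate([p for p, _ in dx][:15],
                               [l for _, l in dx][:15], atlas, k=10)


class TestSubsetEvaluation:
    def test_whole_brain_row_matches_direct_cv(self, atlas, scored):
        profiles, labels = scored
        dx = [(p, l) for p, l in zip(profiles, labels)
              if l in ("AD", "bvFTD")]
        ps, ls = [p for p, _ in dx], [l for _, l in dx]
        wb = npf.whole_brain_subset(atlas)
        table = npf.subset_evaluation(ps, ls, atlas, subsets=[wb], k=5,
                                      seed=6)
        direct = npf.cross_validate(ps, ls, atlas, k=5, seed=6, subset=wb)
        assert table.auc_mean.iloc[0] == pytest.approx(direct.mean("auc"))

    def test_ablation_table_layout(self, atlas):
        subsets = table_subsets(atlas)
        names = [s.name for s in subsets]
        assert names == ["Amygdala", "Hippocampus", "Temporal Lobe",
                         "Frontal Lobe", "Frontal and Temporal Lobe",
                         "Cerebrum", "Whole Brain"]
        cerebrum = set(subsets[-2].expand(atlas))
        assert "cerebellum" not in cerebrum and "brainstem" not in cerebrum
        assert len(subsets[-1].expand(atlas)) == 124


class TestGroupStats:
    def test_identical_groups_null(self):
        ps = [npf.WScoreProfile(str(i), {("r", "volume"): v})
              for i, v in enumerate([1.0, 2.0, 1.0, 2.0])]
        res = npf.group_stats(ps, ["g1", "g1", "g2", "g2"], "r")
        assert res["welch_t"] == pytest.approx(0.0)
        assert res["cohens_d"] == pytest.approx(0.0)

    def test_hand_computed_welch(self):
        """Groups (1,2,3) vs (2,4,6): textbook Welch values."""
        ps = [npf.WScoreProfile(str(i), {("r", "volume"): v})
              for i, v in enumerate([1.0, 2.0, 3.0, 2.0, 4.0, 6.0])]
        labels = ["a"] * 3 + ["b"] * 3
        res = npf.group_stats(ps, labels, "r")
        assert res["welch_t"] == pytest.approx(-1.5491933, abs=1e-6)
        assert res["welch_df"] == pytest.approx(2.9411765, abs=1e-6)
        assert res["cohens_d"] == pytest.approx(-1.2649111, abs=1e-6)
        # two equal-sized groups: ANOVA F equals the pooled t squared
        assert res["anova_F"] == pytest.approx(2.4, abs=1e-9)
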