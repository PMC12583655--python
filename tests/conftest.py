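import numpy as np
import pytest
from hypothesis import settings

import neuroprofile as npf
from neuroprofile.atlas import RegionHierarchy, RegionNode

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atlas():
    return npf.load_default_atlas()


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """Small default-condition cohort with ground truth, shared by tests."""
    cfg = npf.default_config(atlas,
                             n={"HC": 120, "MCI": 0, "AD": 40, "bvFTD": 25},
                             seed=11)
    return npf.generate_cohort(cfg, atlas)


@pytest.fixture(scope="session")
def hc_models(atlas, small_cohort):
    cohort, _truth = small_cohort
    return npf.fit_normative(cohort.subset("HC"), atlas)


@pytest.fixture(scope="session")
def scored(atlas, small_cohort, hc_models):
    cohort, _ = small_cohort
    profiles = npf.score_cohort(cohort, hc_models, atlas)
    labels = [r.diagnosis for r in cohort.records]
    return profiles, labels


@pytest.fixture(scope="session")
def mini_atlas():
    """Three-node hierarchy (root + two cortical leaves) for desk examples."""
    nodes = {
        "root": RegionNode("root", "Root", None, children_ids=["a", "b"],
                           laterality="whole", tissue_class="other",
                           measure_support=frozenset({"volume",
                                                      "thickness"})),
        "a": RegionNode("a", "Leaf A", "root", segmentation_ids=[1],
                        laterality="midline", tissue_class="cortical",
                        order_index=0,
                        measure_support=frozenset({"volume", "thickness"})),
        "b": RegionNode("b", "Leaf B", "root", segmentation_ids=[2],
                        laterality="midline", tissue_class="cortical",
                        order_index=1,
                        measure_support=frozenset({"volume", "thickness"})),
    }
    return RegionHierarchy(nodes=nodes, root_id="root", name="mini")


def brute_force_auc(scores, labels, positive):
    """O(n^2) pairwise-concordance oracle for ROC AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
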