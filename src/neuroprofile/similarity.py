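"""Profile similarity, the Disease Similarity Index, and its evaluation.

A subject's w-score profile is treated as a vector over (region, measure)
entries — parents and leaves together, volume and thickness.  Cosine
similarity to the AD and bvFTD group-mean profiles is combined into the
Disease Similarity Index

    DSimI(x) = cos(x, mean_AD) - cos(x, mean_bvFTD),

thresholded at zero for the differential call (positive -> AD).  Cosine is
magnitude-invariant, so the index responds to the *pattern* of deviating
regions rather than overall severity.  Evaluation uses stratified k-fold
cross-validation with group means refit on training folds only, plus
anatomical-subset ablations (amygdala ... whole brain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .atlas import RegionHierarchy
from .normative import GroupProfile, WScoreProfile, group_mean_profile

MEASURES = ("volume", "thickness")


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class ProfileVector:
    """Ordered (region, measure) keys with their w-scores."""

    keys: tuple[tuple[str, str], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if len(self.keys) != len(self.values):
            raise SimilarityError("keys/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise SimilarityError("non-finite entries in profile vector")

    def __len__(self) -> int:
        return len(self.keys)

    def restrict(self, keys: tuple[tuple[str, str], ...]) -> "ProfileVector":
        index = {k: i for i, k in enumerate(self.keys)}
        return ProfileVector(keys,
                             self.values[[index[k] for k in keys]])


@dataclass
class RegionSubset:
    """Named seed regions expanded to both hemispheres plus descendants."""

    name: str
    seed_region_ids: list[str]

    def expand(self, hierarchy: RegionHierarchy) -> list[str]:
        def mirror(rid: str) -> str | None:
            for a, b in (("lh_", "rh_"), ("left_", "right_")):
                if rid.startswith(a):
                    return b + rid[len(a):]
                if rid.startswith(b):
                    return a + rid[len(b):]
            return None

        seeds: list[str] = []
        for rid in self.seed_region_ids:
            hierarchy.node(rid)
            seeds.append(rid)
            m = mirror(rid)
            if m is not None and m in hierarchy.nodes:
                seeds.append(m)
        expanded: set[str] = set()
        for rid in seeds:
            expanded.add(rid)
            expanded |= hierarchy.descendants(rid)
        if not expanded:
            raise SimilarityError(f"subset {self.name!r} expands to nothing")
        order = {r: i for i, r in enumerate(hierarchy.traversal_order())}
        return sorted(expanded, key=order.__getitem__)


def whole_brain_subset(hierarchy: RegionHierarchy) -> RegionSubset:
    return RegionSubset("Whole Brain", [hierarchy.root_id])


def table_subsets(hierarchy: RegionHierarchy) -> list[RegionSubset]:
    """The ablation ladder from focal structures to the whole brain."""
    return [
        RegionSubset("Amygdala", ["left_amygdala"]),
        RegionSubset("Hippocampus", ["left_hippocampus"]),
        RegionSubset("Temporal Lobe", ["lh_temporal_lobe"]),
        RegionSubset("Frontal Lobe", ["lh_frontal_lobe"]),
        RegionSubset("Frontal and Temporal Lobe",
                     ["lh_frontal_lobe", "lh_temporal_lobe"]),
        RegionSubset("Cerebrum", ["cerebrum"]),
        whole_brain_subset(hierarchy),
    ]


def profile_vector(profile: WScoreProfile | GroupProfile,
                   hierarchy: RegionHierarchy,
                   subset: RegionSubset | None = None,
                   measures: tuple[str, ...] = MEASURES) -> ProfileVector:
    """Canonically ordered vector: volume entries first, then thickness.

    Ordering follows the atlas traversal order and is independent of the
    profile's dict ordering, so two calls always produce identical vectors.
    """
    scores = (profile.mean_scores if isinstance(profile, GroupProfile)
              else profile.scores)
    regions = (subset.expand(hierarchy) if subset is not None
               else hierarchy.traversal_order())
    keys: list[tuple[str, str]] = []
    for measure in MEASURES:
        if measure not in measures:
            continue
        for rid in regions:
            if measure in hierarchy.nodes[rid].measure_support:
                keys.append((rid, measure))
    if not keys:
        raise SimilarityError("empty profile vector (no supported "
                              "region/measure keys)")
    missing = [k for k in keys if k not in scores]
    if missing:
        raise SimilarityError(f"profile does not cover {missing[:5]}")
    return ProfileVector(tuple(keys), np.array([scores[k] for k in keys]))


# ---------------------------------------------------------------------------
# cosine similarity and the index
# ---------------------------------------------------------------------------

def cosine(u: ProfileVector, v: ProfileVector) -> float:
    """Cosine of the angle between two profiles on their shared keys."""
    shared = tuple(k for k in u.keys if k in set(v.keys))
    if not shared:
        raise SimilarityError("profiles share no (region, measure) keys")
    a = u.restrict(shared).values
    b = v.restrict(shared).values
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise SimilarityError("cosine undefined for a zero profile vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def dsimi_from_cosines(cos_ad: float, cos_bvftd: float) -> float:
    """DSimI = cos(x, AD mean) - cos(x, bvFTD mean)."""
    return float(cos_ad) - float(cos_bvftd)


def dsimi(x: ProfileVector, ad_mean: ProfileVector,
          bvftd_mean: ProfileVector) -> float:
    return dsimi_from_cosines(cosine(x, ad_mean), cosine(x, bvftd_mean))


def classify(dsimi_value: float, threshold: float = 0.0) -> str:
    """AD if the index exceeds the threshold, else bvFTD (ties -> bvFTD)."""
    if not np.isfinite(dsimi_value):
        raise SimilarityError(f"non-finite DSimI {dsimi_value!r}")
    return "AD" if dsimi_value > threshold else "bvFTD"


@dataclass
class SimilarityReport:
    subject_id: str
    cos_by_group: dict[str, float]
    dsimi: float
    predicted: str


def similarity_report(profile: WScoreProfile,
                      group_means: dict[str, GroupProfile],
                      hierarchy: RegionHierarchy,
                      subset: RegionSubset | None = None,
                      threshold: float = 0.0) -> SimilarityReport:
    """Cosines to every group mean plus the AD-vs-bvFTD call."""
    x = profile_vector(profile, hierarchy, subset)
    cos_by_group = {
        label: cosine(x, profile_vector(gp, hierarchy, subset))
        for label, gp in group_means.items()}
    d = dsimi_from_cosines(cos_by_group["AD"], cos_by_group["bvFTD"])
    return SimilarityReport(subject_id=profile.subject_id,
                            cos_by_group=cos_by_group, dsimi=d,
                            predicted=classify(d, threshold))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, positive: str = "AD") -> float:
    """ROC AUC via the tie-corrected Mann-Whitney formulation.

    Equals the probability that a random positive outranks a random
    negative (ties counted half); invariant under strictly monotone score
    transforms.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise SimilarityError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class CVResult:
    metrics: pd.DataFrame          # one row per fold
    seed: int
    fold_assignment: np.ndarray    # fold index per subject
    train_means: list[dict[str, dict]] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(self.metrics[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.metrics[metric].std(ddof=1))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m))
                for m in self.metrics.columns}


def _fold_metrics(d_test: np.ndarray, y_test: np.ndarray,
                  positive: str = "bvFTD") -> dict[str, float]:
    predicted = np.array([classify(d) for d in d_test])
    # bvFTD is the minority class and the positive class for sens/spec/F1;
    # DSimI ranks AD high, so the AUC score for bvFTD-positive is -DSimI.
    tp = int(((predicted == positive) & (y_test == positive)).sum())
    fn = int(((predicted != positive) & (y_test == positive)).sum())
    fp = int(((predicted == positive) & (y_test != positive)).sum())
    tn = int(((predicted != positive) & (y_test != positive)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan
    return {
        "auc": roc_auc(-d_test, y_test, positive=positive),
        "balanced_accuracy": (sens + spec) / 2.0,
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
    }


def cross_validate(profiles: list[WScoreProfile], labels: list[str],
                   hierarchy: RegionHierarchy, k: int = 10, seed: int = 0,
                   subset: RegionSubset | None = None) -> CVResult:
    """Stratified k-fold evaluation of the zero-thresholded DSimI rule.

    Group-mean profiles are recomputed from the training subjects of each
    fold only; the threshold is fixed at 0 (never tuned).
    """
    labels = list(labels)
    y = np.asarray(labels)
    for cls in ("AD", "bvFTD"):
        if (y == cls).sum() < k:
            raise SimilarityError(
                f"class {cls!r} has fewer than k={k} members; "
                "use a smaller k")
    vectors = [profile_vector(p, hierarchy, subset) for p in profiles]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.full(len(profiles), -1)
    rows = []
    train_means: list[dict[str, dict]] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_assignment[te] = fold
        means = {}
        for cls in ("AD", "bvFTD"):
            gp = group_mean_profile([profiles[i] for i in tr],
                                    cls, [labels[i] for i in tr])
            means[cls] = profile_vector(gp, hierarchy, subset)
        d_test = np.array([dsimi(vectors[i], means["AD"], means["bvFTD"])
                           for i in te])
        rows.append(_fold_metrics(d_test, y[te]))
        train_means.append({cls: dict(zip(means[cls].keys,
                                          means[cls].values))
                            for cls in means})
    return CVResult(metrics=pd.DataFrame(rows), seed=seed,
                    fold_assignment=fold_assignment,
                    train_means=train_means)


def subset_evaluation(profiles: list[WScoreProfile], labels: list[str],
                      hierarchy: RegionHierarchy,
                      subsets: list[RegionSubset] | None = None,
                      k: int = 10, seed: int = 0) -> pd.DataFrame:
    """One cross-validation per anatomical subset, shared fold assignment."""
    if subsets is None:
        subsets = table_subsets(hierarchy)
    rows = []
    for subset in subsets:
        cv = cross_validate(profiles, labels, hierarchy, k=k, seed=seed,
                            subset=subset)
        rows.append({
            "subset": subset.name,
            "n_regions": len(subset.expand(hierarchy)),
            "auc_mean": cv.mean("auc"), "auc_sd": cv.sd("auc"),
            "balanced_accuracy_mean": cv.mean("balanced_accuracy"),
            "balanced_accuracy_sd": cv.sd("balanced_accuracy"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics (reporting utilities)
# ---------------------------------------------------------------------------

def group_stats(profiles: list[WScoreProfile], labels: list[str],
                region_id: str, measure: str = "volume") -> dict:
    """One-way ANOVA across groups; Welch's t and Cohen's d for two groups."""
    key = (region_id, measure)
    groups: dict[str, list[float]] = {}
    for p, l in zip(profiles, labels):
        groups.setdefault(l, []).append(p.scores[key])
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise SimilarityError("need >= 2 groups with >= 2 subjects each")
    arrays = [np.asarray(v) for v in groups.values()]
    f, p_anova = stats.f_oneway(*arrays)
    out = {"groups": list(groups), "anova_F": float(f),
           "anova_df": (len(arrays) - 1, sum(map(len, arrays)) - len(arrays)),
           "anova_p": float(p_anova)}
    if len(arrays) == 2:
        a, b = arrays
        t_res = stats.ttest_ind(a, b, equal_var=False)
        out["welch_t"] = float(t_res.statistic)
        out["welch_df"] = float(t_res.df)
        out["welch_p"] = float(t_res.pvalue)
        pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                          + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
        out["cohens_d"] = float((a.mean() - b.mean()) / pooled)
    return out
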