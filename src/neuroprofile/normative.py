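"""Normative modeling: healthy-control regression and w-scores.

For every region and measure a linear model is fit on healthy controls
(HC) only,

    measure ~ intercept + age + sex + field_strength + eTIV,

and a subject's deviation is expressed as the w-score

    W = (y - y_hat) / SD(e_controls),

the residual relative to the HC expectation in units of the HC residual
standard deviation.  Negative W means less volume/thickness than expected
(atrophy); positive W means enlargement (the pathological direction for
ventricles).  Measures are first aggregated bottom-up over the anatomy
tree so parents (lobes, hemispheres, whole brain) get their own models and
scores: parent volume is the sum of child volumes; parent thickness is the
surface-area-weighted mean thickness of cortical descendants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import RegionHierarchy
from .io import Cohort, FIELD_CODE, SEX_CODE, SubjectRecord

COVARIATE_NAMES = ("intercept", "age", "sex", "field_strength", "etiv")


class NormativeError(ValueError):
    pass


@dataclass(frozen=True)
class CovariateVector:
    """Confounds controlled for by the normative regression."""

    age: float
    sex_code: float          # female = 0, male = 1
    field_code: float        # 1.5 T = 0, 3 T = 1
    etiv: float              # mm^3

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise NormativeError(f"non-finite covariates: {self}")
        if self.age <= 0 or self.etiv <= 0:
            raise NormativeError("age and eTIV must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([1.0, self.age, self.sex_code, self.field_code,
                         self.etiv])

    @classmethod
    def from_record(cls, record: SubjectRecord) -> "CovariateVector":
        return cls(age=record.age, sex_code=SEX_CODE[record.sex],
                   field_code=FIELD_CODE[record.field_strength],
                   etiv=record.etiv)


@dataclass
class NormativeModel:
    """OLS fit for one (region, measure): raw-scale coefficients + HC SD."""

    region_id: str
    measure: str
    coefficients: np.ndarray     # (5,) intercept, age, sex, field, etiv
    residual_sd: float           # SD of HC residuals, ddof=1
    n_train: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(COVARIATE_NAMES),):
            raise NormativeError(
                f"{self.region_id}/{self.measure}: expected "
                f"{len(COVARIATE_NAMES)} coefficients")
        if not self.residual_sd > 0:
            raise NormativeError(
                f"{self.region_id}/{self.measure}: residual_sd must be > 0")
        if self.n_train < len(COVARIATE_NAMES) + 2:
            raise NormativeError(
                f"{self.region_id}/{self.measure}: too few training "
                f"subjects (n={self.n_train})")

    def predict(self, cov: CovariateVector) -> float:
        return float(self.coefficients @ cov.as_array())


@dataclass
class NormativeModelSet:
    """Models keyed by (region_id, measure), fit on HC only."""

    models: dict[tuple[str, str], NormativeModel]
    hc_only: bool = True
    provenance: str = ""

    def __getitem__(self, key: tuple[str, str]) -> NormativeModel:
        return self.models[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.models

    def validate_complete(self, hierarchy: RegionHierarchy) -> None:
        for rid in hierarchy.traversal_order():
            if (rid, "volume") not in self.models:
                raise NormativeError(f"no volume model for {rid}")
        for rid in hierarchy.thickness_ids():
            if (rid, "thickness") not in self.models:
                raise NormativeError(f"no thickness model for {rid}")


@dataclass
class WScoreProfile:
    """Per-(region, measure) w-scores for a subject; raw measures retained."""

    subject_id: str
    scores: dict[tuple[str, str], float]
    raw_values: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class GroupProfile:
    """Entrywise mean w-score profile of a diagnosis group."""

    label: str
    mean_scores: dict[tuple[str, str], float]
    n: int

    def as_profile(self) -> WScoreProfile:
        return WScoreProfile(subject_id=f"mean[{self.label}]",
                             scores=dict(self.mean_scores))


# ---------------------------------------------------------------------------
# aggregation over the anatomy tree
# ---------------------------------------------------------------------------

def aggregate_to_parents(record: SubjectRecord,
                         hierarchy: RegionHierarchy
                         ) -> tuple[dict[str, float], dict[str, float]]:
    """Extend leaf measures to every node of the hierarchy.

    Returns ``(volumes, thicknesses)`` over all nodes (thickness only where
    supported).  Parent volume is the sum over children; parent thickness is
    the surface-area-weighted mean over cortical leaf descendants when areas
    are available for all of them, otherwise the unweighted mean.
    """
    volumes = dict(record.volumes)
    thick = dict(record.thicknesses)
    order = hierarchy.traversal_order()
    for rid in reversed(order):            # children before parents
        node = hierarchy.nodes[rid]
        if node.is_leaf:
            continue
        volumes[rid] = sum(volumes[c] for c in node.children_ids)
        if "thickness" in node.measure_support:
            leaves = [l for l in hierarchy.leaves_under(rid)
                      if l in record.thicknesses]
            if all(l in record.areas for l in leaves):
                w = np.array([record.areas[l] for l in leaves])
            else:
                w = np.ones(len(leaves))
            t = np.array([record.thicknesses[l] for l in leaves])
            thick[rid] = float(np.average(t, weights=w))
    return volumes, thick


# ---------------------------------------------------------------------------
# fitting and scoring
# ---------------------------------------------------------------------------

def design_matrix(records: list[SubjectRecord]) -> np.ndarray:
    return np.stack([CovariateVector.from_record(r).as_array()
                     for r in records])


def _check_design(X: np.ndarray) -> None:
    for j, name in enumerate(COVARIATE_NAMES[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise NormativeError(
                f"degenerate design: covariate {name!r} is constant in the "
                "training cohort")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NormativeError("rank-deficient design matrix")


def fit_normative(hc: Cohort, hierarchy: RegionHierarchy,
                  ddof: int = 1) -> NormativeModelSet:
    """Fit per-(region, measure) OLS models on a healthy-control cohort.

    ``residual_sd`` is the sample SD (``ddof`` defaults to 1) of the HC
    residuals, the denominator of the w-score.  Deterministic: no
    randomness is involved, and row order does not matter.
    """
    non_hc = [r.subject_id for r in hc.records if r.diagnosis != "HC"]
    if non_hc:
        raise NormativeError(f"training cohort must be HC only; found "
                             f"{non_hc[:5]}")
    n = len(hc.records)
    if n < 10:
        raise NormativeError(f"need at least 10 HC subjects, got {n}")
    X = design_matrix(hc.records)
    _check_design(X)

    agg = [aggregate_to_parents(r, hierarchy) for r in hc.records]
    models: dict[tuple[str, str], NormativeModel] = {}

    def fit_one(rid: str, measure: str, y: np.ndarray) -> None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = float(np.std(resid, ddof=ddof))
        if not sd > 0:
            raise NormativeError(f"{rid}/{measure}: zero residual SD")
        models[(rid, measure)] = NormativeModel(
            region_id=rid, measure=measure, coefficients=beta,
            residual_sd=sd, n_train=n)

    for rid in hierarchy.traversal_order():
        fit_one(rid, "volume", np.array([a[0][rid] for a in agg]))
    for rid in hierarchy.thickness_ids():
        fit_one(rid, "thickness", np.array([a[1][rid] for a in agg]))
    return NormativeModelSet(models=models, hc_only=True,
                             provenance=hc.provenance)


def w_score(y: float, model: NormativeModel, cov: CovariateVector) -> float:
    """W = (y - y_hat) / SD(e_controls); negative = atrophy."""
    if not np.isfinite(y):
        raise NormativeError(f"non-finite measure value {y!r}")
    return (float(y) - model.predict(cov)) / model.residual_sd


def compute_wscore_profile(record: SubjectRecord,
                           models: NormativeModelSet,
                           hierarchy: RegionHierarchy) -> WScoreProfile:
    """Aggregate the record bottom-up, then score every node/measure."""
    models.validate_complete(hierarchy)
    cov = CovariateVector.from_record(record)
    volumes, thick = aggregate_to_parents(record, hierarchy)
    scores: dict[tuple[str, str], float] = {}
    raw: dict[tuple[str, str], float] = {}
    for rid in hierarchy.traversal_order():
        scores[(rid, "volume")] = w_score(volumes[rid],
                                          models[(rid, "volume")], cov)
        raw[(rid, "volume")] = volumes[rid]
    for rid in hierarchy.thickness_ids():
        scores[(rid, "thickness")] = w_score(thick[rid],
                                             models[(rid, "thickness")], cov)
        raw[(rid, "thickness")] = thick[rid]
    return WScoreProfile(subject_id=record.subject_id, scores=scores,
                         raw_values=raw)


def score_cohort(cohort: Cohort, models: NormativeModelSet,
                 hierarchy: RegionHierarchy) -> list[WScoreProfile]:
    return [compute_wscore_profile(r, models, hierarchy)
            for r in cohort.records]


def group_mean_profile(profiles: list[WScoreProfile], label: str,
                       labels: list[str] | None = None) -> GroupProfile:
    """Entrywise mean w-score profile over the subjects with ``label``.

    If ``labels`` is omitted, all profiles are averaged under ``label``.
    """
    if labels is not None:
        selected = [p for p, l in zip(profiles, labels) if l == label]
    else:
        selected = list(profiles)
    if not selected:
        raise NormativeError(f"no profiles with label {label!r}")
    keys = set(selected[0].scores)
    for p in selected[1:]:
        if set(p.scores) != keys:
            raise NormativeError("profiles have mismatched key sets")
    mean = {k: float(np.mean([p.scores[k] for p in selected]))
            for k in selected[0].scores}
    return GroupProfile(label=label, mean_scores=mean, n=len(selected))
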