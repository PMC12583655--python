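"""Synthetic multi-cohort generator with retained ground truth.

The restricted source cohorts (HC / amnestic MCI / AD / bvFTD) are emulated
by a generative model matching the normative engine's model class: each leaf
measure is a linear function of age, sex, field strength and eTIV plus a
diagnosis-specific shift of δ healthy-residual SDs and Gaussian noise.

The noise has a shared per-subject component,

    ε_i = σ_i (ρ g + sqrt(1 - ρ²) e_i),   g, e_i ~ N(0, 1) iid,

with ρ = 0.95 by default: regional residuals around the covariate
expectation are strongly correlated within a subject (a global
"brain-reserve/atrophy" factor), which is what makes a uniform leaf-level
effect reappear at the aggregated parent with a comparable w-score.  Each
region's marginal residual SD is still exactly σ_i.

Covariate distributions default to the source cohorts' demographics
(e.g. AD age 74.1 ± 7.7 y, bvFTD 62.8 ± 8.2 y; bvFTD 35.4% female).
Effect maps are qualitative design choices: AD = temporal-lobe atrophy with
inferior-lateral-ventricle enlargement and mild parietal spread; bvFTD =
frontal plus temporal atrophy; MCI = medial-temporal-restricted AD map
scaled by 0.4.  Ground truth (coefficients, σ, δ) is returned with every
cohort so recovery tests can compare against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .atlas import RegionHierarchy, load_default_atlas
from .io import Cohort, SubjectRecord

#: fixed internal seed for the ground-truth parameter draw; independent of
#: the cohort-sampling seed so "the population" is stable across runs.
_PARAM_SEED = 761_204_993

DIAGNOSES = ("HC", "MCI", "AD", "bvFTD")


class SyntheticError(ValueError):
    pass


@dataclass
class EffectMap:
    """δ shifts in HC-residual-SD units per diagnosis and (region, measure)."""

    deltas: dict[str, dict[tuple[str, str], float]]

    def __post_init__(self) -> None:
        self.deltas.setdefault("HC", {})
        if any(self.deltas["HC"].values()):
            raise SyntheticError("HC effect map must be all-zero")

    def delta(self, diagnosis: str, region_id: str, measure: str) -> float:
        return self.deltas.get(diagnosis, {}).get((region_id, measure), 0.0)


@dataclass
class GroundTruth:
    """Generative parameters retained for recovery tests."""

    coefficients: dict[tuple[str, str], np.ndarray]   # (leaf, measure) -> (5,)
    residual_sd: dict[tuple[str, str], float]
    mean_area: dict[str, float]                       # cortical leaf -> mm^2
    effects: EffectMap


@dataclass
class GeneratorConfig:
    n: dict[str, int]
    age: dict[str, tuple[float, float]]               # mean, sd (years)
    sex_female: dict[str, float]                      # P(female)
    p_3t: dict[str, float]                            # P(3 T scanner)
    etiv: dict[str, tuple[float, float]]              # mean, sd (mm^3)
    effects: EffectMap
    shared_noise_rho: float = 0.95
    nonlinear_age: bool = False
    seed: int = 0
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        for label, nn in self.n.items():
            if nn < 0:
                raise SyntheticError(f"negative n for {label}")
        for label, (m, s) in self.age.items():
            if s <= 0 or m <= 0:
                raise SyntheticError(f"bad age distribution for {label}")
        for label, (m, s) in self.etiv.items():
            if s <= 0 or m <= 0:
                raise SyntheticError(f"bad eTIV distribution for {label}")
        if not 0.0 <= self.shared_noise_rho < 1.0:
            raise SyntheticError("shared_noise_rho must be in [0, 1)")
        if self.seed is None:
            raise SyntheticError("seed is mandatory")


# ---------------------------------------------------------------------------
# ground-truth population parameters
# ---------------------------------------------------------------------------

_BASE_VOLUME_RANGE = {                     # mm^3, by tissue class
    "cortical": (2_000.0, 12_000.0),
    "subcortical-gray": (1_200.0, 8_000.0),
    "white-matter": (800.0, 240_000.0),
    "ventricular": (600.0, 14_000.0),
    "cerebellar": (12_000.0, 55_000.0),
    "brainstem": (18_000.0, 24_000.0),
    "other": (1_000.0, 5_000.0),
}

_REF_AGE, _REF_ETIV = 70.0, 1.5e6


def _ground_truth(hierarchy: RegionHierarchy) -> GroundTruth:
    rng = np.random.default_rng(_PARAM_SEED)
    coef: dict[tuple[str, str], np.ndarray] = {}
    sd: dict[tuple[str, str], float] = {}
    area: dict[str, float] = {}
    for rid in hierarchy.leaf_ids:
        node = hierarchy.nodes[rid]
        lo, hi = _BASE_VOLUME_RANGE[node.tissue_class]
        v0 = float(rng.uniform(lo, hi))
        b_age = -0.003 * v0                 # mm^3 per year: shrinkage
        b_sex = 0.03 * v0
        b_field = 0.005 * v0
        b_etiv = 0.40 * v0 / _REF_ETIV      # positive head-size scaling
        icpt = v0 - (b_age * _REF_AGE + b_field + b_etiv * _REF_ETIV)
        coef[(rid, "volume")] = np.array(
            [icpt, b_age, b_sex, b_field, b_etiv])
        sd[(rid, "volume")] = 0.06 * v0
        if node.tissue_class == "cortical":
            t0 = float(rng.uniform(2.0, 3.2))
            tb_age, tb_sex, tb_field, tb_etiv = -0.010, 0.02, 0.01, 0.0
            ticpt = t0 - (tb_age * _REF_AGE + tb_field + tb_etiv * _REF_ETIV)
            coef[(rid, "thickness")] = np.array(
                [ticpt, tb_age, tb_sex, tb_field, tb_etiv])
            sd[(rid, "thickness")] = 0.12
            area[rid] = float(rng.uniform(800.0, 6_000.0))
    return GroundTruth(coefficients=coef, residual_sd=sd, mean_area=area,
                       effects=EffectMap({"HC": {}}))


def default_effect_map(hierarchy: RegionHierarchy) -> EffectMap:
    """Qualitative disease atrophy patterns in residual-SD units."""
    def cortical_leaves(lobe: str) -> list[str]:
        return sorted(hierarchy.leaves_under(f"lh_{lobe}")
                      | hierarchy.leaves_under(f"rh_{lobe}"))

    temporal = cortical_leaves("temporal_lobe")
    frontal = cortical_leaves("frontal_lobe")
    parietal = cortical_leaves("parietal_lobe")

    ad: dict[tuple[str, str], float] = {}
    for rid in temporal:
        ad[(rid, "volume")] = -2.0
        ad[(rid, "thickness")] = -2.0
    for rid in parietal:
        ad[(rid, "volume")] = -0.8
        ad[(rid, "thickness")] = -0.8
    for side in ("left", "right"):
        ad[(f"{side}_hippocampus", "volume")] = -2.5
        ad[(f"{side}_amygdala", "volume")] = -2.0
        ad[(f"{side}_inferior_lateral_ventricle", "volume")] = 2.0

    medial_temporal = {"lh_entorhinal", "rh_entorhinal",
                       "lh_parahippocampal", "rh_parahippocampal"}
    mci = {k: 0.4 * v for k, v in ad.items()
           if k[0] in medial_temporal
           or k[0].endswith(("hippocampus", "amygdala"))}

    bv: dict[tuple[str, str], float] = {}
    for rid in frontal:
        bv[(rid, "volume")] = -2.5
        bv[(rid, "thickness")] = -2.5
    for rid in temporal:
        bv[(rid, "volume")] = -2.0
        bv[(rid, "thickness")] = -2.0
    for side in ("left", "right"):
        bv[(f"{side}_hippocampus", "volume")] = -2.0
        bv[(f"{side}_amygdala", "volume")] = -2.0

    return EffectMap({"HC": {}, "MCI": mci, "AD": ad, "bvFTD": bv})


def default_config(hierarchy: RegionHierarchy | None = None,
                   n: dict[str, int] | None = None,
                   seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults: source-cohort demographics, scaled-down n.

    Group sizes keep the source cohorts' AD:bvFTD imbalance (~2.5:1) at a
    size every test can afford; pass ``n`` to override per group.
    """
    if hierarchy is None:
        hierarchy = load_default_atlas()
    sizes = {"HC": 400, "MCI": 150, "AD": 150, "bvFTD": 60}
    if n:
        sizes.update(n)
    cfg = GeneratorConfig(
        n=sizes,
        age={"HC": (70.4, 7.6), "MCI": (72.5, 7.4),
             "AD": (74.1, 7.7), "bvFTD": (62.8, 8.2)},
        sex_female={"HC": 0.567, "MCI": 0.445, "AD": 0.511, "bvFTD": 0.354},
        p_3t={d: 0.7 for d in DIAGNOSES},
        etiv={d: (1.45e6, 1.4e5) for d in DIAGNOSES},
        effects=default_effect_map(hierarchy),
        seed=seed,
    )
    cfg.truth = _ground_truth(hierarchy)
    cfg.truth.effects = cfg.effects
    return cfg


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig,
                    hierarchy: RegionHierarchy | None = None
                    ) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from the generative model; deterministic given seed."""
    if hierarchy is None:
        hierarchy = load_default_atlas()
    truth = config.truth or _ground_truth(hierarchy)
    if config.truth is None:
        truth.effects = config.effects
    rng = np.random.default_rng(config.seed)
    rho = config.shared_noise_rho
    indep = np.sqrt(1.0 - rho * rho)
    records: list[SubjectRecord] = []
    counter = 0
    for diagnosis in DIAGNOSES:
        for _ in range(config.n.get(diagnosis, 0)):
            counter += 1
            sid = f"syn{counter:05d}"
            mu_a, sd_a = config.age[diagnosis]
            age = float(np.clip(rng.normal(mu_a, sd_a), 40.0, 95.0))
            sex = "female" if rng.random() < config.sex_female[diagnosis] \
                else "male"
            fs = 3.0 if rng.random() < config.p_3t[diagnosis] else 1.5
            mu_e, sd_e = config.etiv[diagnosis]
            etiv = float(max(rng.normal(mu_e, sd_e), 9.0e5))
            x = np.array([1.0, age, 1.0 if sex == "male" else 0.0,
                          1.0 if fs == 3.0 else 0.0, etiv])
            g = rng.standard_normal()        # shared residual factor
            volumes: dict[str, float] = {}
            thick: dict[str, float] = {}
            areas: dict[str, float] = {}
            for rid in hierarchy.leaf_ids:
                for measure in ("volume", "thickness"):
                    key = (rid, measure)
                    if key not in truth.coefficients:
                        continue
                    beta = truth.coefficients[key]
                    sigma = truth.residual_sd[key]
                    y = float(beta @ x)
                    if config.nonlinear_age:
                        # mild concavity: extra loss accelerating past 70 y
                        y -= 0.02 * sigma * max(age - 70.0, 0.0) ** 2 / 10.0
                    y += config.effects.delta(diagnosis, rid, measure) * sigma
                    y += sigma * (rho * g + indep * rng.standard_normal())
                    if measure == "volume":
                        volumes[rid] = max(y, 1.0)
                    else:
                        thick[rid] = float(np.clip(y, 0.5, 5.0))
                if rid in truth.mean_area:
                    areas[rid] = float(max(
                        truth.mean_area[rid] * (1 + 0.05
                                                * rng.standard_normal()),
                        50.0))
            records.append(SubjectRecord(
                subject_id=sid, diagnosis=diagnosis, age=age, sex=sex,
                field_strength=fs, etiv=etiv, volumes=volumes,
                thicknesses=thick, areas=areas, cohort="synthetic"))
    return Cohort(records, provenance=f"synthetic(seed={config.seed})"), truth


# ---------------------------------------------------------------------------
# stats-file fixtures (tests the segmentation-stats reader)
# ---------------------------------------------------------------------------

_APARC_COLS = ("StructName NumVert SurfArea GrayVol ThickAvg ThickStd "
               "MeanCurv GausCurv FoldInd CurvInd")
_ASEG_COLS = "Index SegId NVoxels Volume_mm3 StructName"


def make_fixture_stats_dir(record: SubjectRecord, path: str | Path,
                           hierarchy: RegionHierarchy | None = None) -> Path:
    """Write aseg-style + aparc-DKT-style stats files reproducing ``record``.

    Volumes are printed with 1 decimal, thickness with 3, area as integers
    (the source tools' precision); parsing the directory back reproduces the
    record to that precision.
    """
    if hierarchy is None:
        hierarchy = load_default_atlas()
    path = Path(path)
    stats = path / "stats"
    stats.mkdir(parents=True, exist_ok=True)

    cortical = set(hierarchy.cortical_leaves())
    aseg_lines = [
        "# Title Segmentation Statistics",
        f"# subjectname {record.subject_id}",
        "# Measure EstimatedTotalIntraCranialVol, eTIV, "
        f"Estimated Total Intracranial Volume, {record.etiv:.6f}, mm^3",
        f"# ColHeaders {_ASEG_COLS}",
    ]
    idx = 0
    for rid in hierarchy.leaf_ids:
        if rid in cortical:
            continue
        node = hierarchy.nodes[rid]
        idx += 1
        vol = record.volumes[rid]
        aseg_lines.append(
            f"{idx:3d} {node.segmentation_ids[0]:4d} {int(vol):7d} "
            f"{vol:10.1f}  {node.struct_names[0]}")
    (stats / "aseg.stats").write_text("\n".join(aseg_lines) + "\n")

    for hemi in ("lh", "rh"):
        lines = [
            "# Table of FreeSurfer cortical parcellation anatomical "
            "statistics",
            f"# subjectname {record.subject_id}",
            f"# hemi {hemi}",
            f"# ColHeaders {_APARC_COLS}",
        ]
        for rid in hierarchy.leaf_ids:
            if rid not in cortical or not rid.startswith(f"{hemi}_"):
                continue
            node = hierarchy.nodes[rid]
            area = record.areas.get(rid, 1000.0)
            lines.append(
                f"{node.struct_names[0]:<28s} {int(area * 2):6d} "
                f"{int(round(area)):6d} {record.volumes[rid]:8.1f} "
                f"{record.thicknesses[rid]:6.3f} 0.500 0.100 0.020 10 1.0")
        (stats / f"{hemi}.aparc.DKTatlas.stats").write_text(
            "\n".join(lines) + "\n")
    return path
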