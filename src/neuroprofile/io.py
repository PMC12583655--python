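"""Cohort ingestion and profile output.

Two input routes are supported: a canonical wide table (one row per subject,
``<region_id>__volume`` / ``__thickness`` / ``__area`` columns) and the
stats-file dialect written by FreeSurfer/FastSurfer (an aseg-style file plus
left/right aparc-DKT-style files per subject).  Both yield the same
:class:`SubjectRecord`.  Units are fixed: mm³ (volume, eTIV), mm (thickness),
mm² (area), years (age), tesla (field strength).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atlas import RegionHierarchy

DIAGNOSES = ("HC", "MCI", "AD", "bvFTD", "other")
_DIAG_ALIASES = {
    "hc": "HC", "control": "HC", "cn": "HC", "healthy": "HC",
    "mci": "MCI", "amci": "MCI",
    "ad": "AD", "dementia": "AD", "alzheimer": "AD",
    "bvftd": "bvFTD", "ftd": "bvFTD",
}

#: covariate encodings used throughout the normative engine
SEX_CODE = {"female": 0.0, "male": 1.0}
FIELD_CODE = {1.5: 0.0, 3.0: 1.0}


class CohortError(ValueError):
    """Integrity or completeness failure while reading subject data."""


def normalize_diagnosis(label: str) -> str:
    key = str(label).strip()
    if key in DIAGNOSES:
        return key
    norm = _DIAG_ALIASES.get(key.lower())
    if norm is None:
        return "other"
    return norm


@dataclass
class SubjectRecord:
    """Covariates plus leaf-level measures for one subject (first scan only)."""

    subject_id: str
    diagnosis: str
    age: float
    sex: str                       # "female" | "male"
    field_strength: float          # tesla, 1.5 or 3.0
    etiv: float                    # mm^3
    volumes: dict[str, float]      # leaf region_id -> mm^3
    thicknesses: dict[str, float] = field(default_factory=dict)
    areas: dict[str, float] = field(default_factory=dict)
    cohort: str = ""

    def validate(self, hierarchy: RegionHierarchy) -> None:
        if self.etiv <= 0:
            raise CohortError(f"{self.subject_id}: eTIV must be > 0")
        if self.sex not in SEX_CODE:
            raise CohortError(f"{self.subject_id}: sex must be female/male, "
                              f"got {self.sex!r}")
        if self.field_strength not in FIELD_CODE:
            raise CohortError(
                f"{self.subject_id}: field strength must be 1.5 or 3.0 T "
                f"(binary covariate), got {self.field_strength!r}")
        leaves = set(hierarchy.leaf_ids)
        cortical = set(hierarchy.cortical_leaves())
        for key in (set(self.volumes) | set(self.thicknesses)
                    | set(self.areas)):
            if key not in leaves:
                raise CohortError(f"{self.subject_id}: measure key {key!r} "
                                  "is not an atlas leaf")
        missing = leaves - set(self.volumes)
        if missing:
            raise CohortError(
                f"{self.subject_id}: missing volumes for "
                f"{sorted(missing)}")
        missing_t = cortical - set(self.thicknesses)
        if missing_t:
            raise CohortError(
                f"{self.subject_id}: missing thickness for "
                f"{sorted(missing_t)}")
        for rid, v in self.volumes.items():
            if not v > 0:
                raise CohortError(f"{self.subject_id}: non-positive volume "
                                  f"for {rid}")
        for rid, t in self.thicknesses.items():
            if not 0.5 <= t <= 5.0:
                warnings.warn(
                    f"{self.subject_id}: thickness {t:.3f} mm for {rid} "
                    "outside the plausible 0.5-5.0 mm band", stacklevel=2)


@dataclass
class Cohort:
    records: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise CohortError(f"duplicate subject_id(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, diagnosis: str) -> "Cohort":
        return Cohort([r for r in self.records if r.diagnosis == diagnosis],
                      provenance=self.provenance)

    def to_table(self, hierarchy: RegionHierarchy) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "subject_id": r.subject_id, "cohort": r.cohort,
                "diagnosis": r.diagnosis, "age": r.age, "sex": r.sex,
                "field_strength": r.field_strength, "etiv": r.etiv,
            }
            for rid in hierarchy.leaf_ids:
                row[f"{rid}__volume"] = r.volumes[rid]
            for rid in hierarchy.cortical_leaves():
                row[f"{rid}__thickness"] = r.thicknesses[rid]
                if rid in r.areas:
                    row[f"{rid}__area"] = r.areas[rid]
            rows.append(row)
        return pd.DataFrame(rows)


def read_subject_table(path: str | Path,
                       hierarchy: RegionHierarchy) -> Cohort:
    """Read the canonical wide CSV/TSV into a validated :class:`Cohort`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "diagnosis", "age", "sex", "field_strength",
                "etiv"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CohortError(f"missing required columns: "
                          f"{sorted(missing_cols)}")
    leaves = hierarchy.leaf_ids
    cortical = hierarchy.cortical_leaves()
    missing_v = [r for r in leaves if f"{r}__volume" not in df.columns]
    missing_t = [r for r in cortical
                 if f"{r}__thickness" not in df.columns]
    if missing_v or missing_t:
        raise CohortError(
            "missing measure columns; volumes: "
            f"{missing_v}; thicknesses: {missing_t}")
    records = []
    for idx, row in df.iterrows():
        try:
            volumes = {r: float(row[f"{r}__volume"]) for r in leaves}
            thick = {r: float(row[f"{r}__thickness"]) for r in cortical}
            areas = {r: float(row[f"{r}__area"]) for r in cortical
                     if f"{r}__area" in df.columns
                     and pd.notna(row.get(f"{r}__area"))}
            rec = SubjectRecord(
                subject_id=str(row["subject_id"]),
                cohort=str(row.get("cohort", "") or ""),
                diagnosis=normalize_diagnosis(row["diagnosis"]),
                age=float(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                field_strength=float(row["field_strength"]),
                etiv=float(row["etiv"]),
                volumes=volumes, thicknesses=thick, areas=areas)
        except (TypeError, ValueError) as exc:
            raise CohortError(
                f"non-numeric value in row {idx} "
                f"(subject {row.get('subject_id')}): {exc}") from exc
        rec.validate(hierarchy)
        records.append(rec)
    return Cohort(records, provenance=str(path))


def write_subject_table(cohort: Cohort, hierarchy: RegionHierarchy,
                        path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cohort.to_table(hierarchy).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# FreeSurfer / FastSurfer stats dialect
# ---------------------------------------------------------------------------

def _parse_stats_file(path: Path) -> tuple[dict[str, float],
                                           list[dict[str, str]]]:
    """Parse one stats file -> (header measures, table rows by column name)."""
    measures: dict[str, float] = {}
    columns: list[str] = []
    rows: list[dict[str, str]] = []
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("Measure"):
                    parts = [p.strip() for p in body[len("Measure"):]
                             .lstrip(" ").split(",")]
                    # Measure <key>, <name>, <description>, <value>, <unit>
                    if len(parts) >= 4:
                        try:
                            measures[parts[0]] = float(parts[-2])
                        except ValueError:
                            pass
                elif body.startswith("ColHeaders"):
                    columns = body.split()[1:]
                continue
            if not line.strip():
                continue
            fields = line.split()
            if not columns:
                raise CohortError(f"{path}: table row before ColHeaders")
            if len(fields) != len(columns):
                raise CohortError(f"{path}: row has {len(fields)} fields, "
                                  f"expected {len(columns)}")
            rows.append(dict(zip(columns, fields)))
    return measures, rows


def read_segmentation_stats(subject_dir: str | Path,
                            hierarchy: RegionHierarchy,
                            subject_id: str | None = None,
                            **covariates) -> SubjectRecord:
    """Build a :class:`SubjectRecord` from a subject's stats directory.

    Expects ``aseg.stats``, ``lh.aparc.DKTatlas.stats`` and
    ``rh.aparc.DKTatlas.stats`` in ``subject_dir`` (a ``stats/`` subdirectory
    is also searched).  Covariates that segmentation does not provide
    (diagnosis, age, sex, field_strength) are passed as keyword arguments.
    """
    subject_dir = Path(subject_dir)
    stats_dir = subject_dir / "stats" if (subject_dir / "stats").is_dir() \
        else subject_dir

    def find(name: str) -> Path:
        p = stats_dir / name
        if not p.exists():
            raise CohortError(f"missing required stats file {name} "
                              f"in {stats_dir}")
        return p

    aseg = find("aseg.stats")
    aparc = {"lh": find("lh.aparc.DKTatlas.stats"),
             "rh": find("rh.aparc.DKTatlas.stats")}

    name_map = hierarchy.struct_name_lookup()
    volumes: dict[str, float] = {}
    thicknesses: dict[str, float] = {}
    areas: dict[str, float] = {}

    measures, rows = _parse_stats_file(aseg)
    etiv = measures.get("EstimatedTotalIntraCranialVol")
    if etiv is None:
        raise CohortError(f"{aseg}: no EstimatedTotalIntraCranialVol "
                          "Measure line")
    for row in rows:
        struct = row.get("StructName", "")
        rid = name_map.get(struct.lower())
        if rid is None:
            warnings.warn(f"{aseg.name}: structure {struct!r} not in atlas; "
                          "ignored", stacklevel=2)
            continue
        volumes[rid] = float(row["Volume_mm3"])

    for hemi, path in aparc.items():
        _, rows = _parse_stats_file(path)
        for row in rows:
            struct = row.get("StructName", "")
            # hemisphere is implied by the file, not the row name
            rid = f"{hemi}_{struct}".lower()
            if rid not in hierarchy.nodes:
                rid = name_map.get(struct.lower())
            if rid is None:
                warnings.warn(
                    f"{path.name}: structure {struct!r} not in atlas; "
                    "ignored", stacklevel=2)
                continue
            volumes[rid] = float(row["GrayVol"])
            thicknesses[rid] = float(row["ThickAvg"])
            areas[rid] = float(row["SurfArea"])

    rec = SubjectRecord(
        subject_id=subject_id or subject_dir.name,
        diagnosis=normalize_diagnosis(covariates.get("diagnosis", "other")),
        age=float(covariates.get("age", float("nan"))),
        sex=str(covariates.get("sex", "female")),
        field_strength=float(covariates.get("field_strength", 3.0)),
        etiv=etiv, volumes=volumes, thicknesses=thicknesses, areas=areas,
        cohort=str(covariates.get("cohort", "")))
    missing = set(hierarchy.leaf_ids) - set(volumes)
    if missing:
        raise CohortError(f"{subject_dir}: atlas leaves with no source row: "
                          f"{sorted(missing)}")
    rec.validate(hierarchy)
    return rec


# ---------------------------------------------------------------------------
# w-score profile output (long format)
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format table (subject_id, region_id, measure, value, wscore)."""
    key_sets = {frozenset(p.scores) for p in profiles}
    if len(key_sets) > 1:
        raise CohortError("profiles do not share one atlas/key set")
    rows = []
    for p in profiles:
        for (rid, measure), w in p.scores.items():
            rows.append({"subject_id": p.subject_id, "region_id": rid,
                         "measure": measure,
                         "value": p.raw_values.get((rid, measure)),
                         "wscore": w})
    return pd.DataFrame(rows, columns=["subject_id", "region_id", "measure",
                                       "value", "wscore"])


def write_profiles(profiles, path: str | Path, format: str = "csv") -> None:
    """Write w-score profiles as long CSV or JSON; lossless reload."""
    df = profiles_to_frame(profiles)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown profile format {format!r}")


def read_profiles(path: str | Path):
    from .normative import WScoreProfile  # local import: avoid cycle

    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()),
                          columns=["subject_id", "region_id", "measure",
                                   "value", "wscore"])
    else:
        df = pd.read_csv(path)
    profiles = []
    if df.empty:
        return profiles
    for sid, grp in df.groupby("subject_id", sort=False):
        scores = {(r.region_id, r.measure): float(r.wscore)
                  for r in grp.itertuples()}
        raw = {(r.region_id, r.measure): float(r.value)
               for r in grp.itertuples() if pd.notna(r.value)}
        profiles.append(WScoreProfile(subject_id=str(sid), scores=scores,
                                      raw_values=raw))
    return profiles
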