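"""Subject tables, FreeSurfer stats parsing and cohort filters.

This module turns raw inputs — a delimited per-visit subject table and/or
FreeSurfer ``aseg.stats`` / ``?h.aparc.stats`` outputs — into a validated
:class:`Dataset` whose feature columns are relative volumes (% of total
intracranial volume, bilaterally averaged) and surface measures, and
applies the study's inclusion filters (segmentation failures, diagnostic
converters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DomainError,
    InputError,
    ParseError,
    SchemaError,
    ValidationError,
)
from .features import DK_REGIONS, default_feature_names
from .scales import SCALES, TESTS

__all__ = [
    "SubjectRecord",
    "Dataset",
    "RawVolumes",
    "FilterResult",
    "load_subject_table",
    "write_subject_table",
    "parse_freesurfer_stats",
    "compute_relative_volumes",
    "build_feature_vector",
    "apply_cohort_filters",
    "COHORTS",
]

#: Diagnostic classes in increasing order of severity.
COHORTS: tuple[str, ...] = ("CN", "MCI", "Dementia")

AGE_BOUNDS = (40.0, 110.0)

#: Cohort label spellings accepted out of the box (extendable via schema).
DEFAULT_COHORT_ALIASES: dict[str, str] = {
    "CN": "CN",
    "NL": "CN",
    "CONTROL": "CN",
    "MCI": "MCI",
    "EMCI": "MCI",
    "LMCI": "MCI",
    "DEMENTIA": "Dementia",
    "AD": "Dementia",
}

DEMOGRAPHIC_COLUMNS = ("subject_id", "visit_index", "age", "sex", "education", "cohort")


@dataclass(frozen=True)
class SubjectRecord:
    """One visit of one subject: demographics, label, morphometry, scores."""

    subject_id: str
    visit_index: int
    age: float
    sex: str | None
    education: float | None
    cohort: str
    features: pd.Series
    scores: dict[str, float]


@dataclass
class Dataset:
    """An analysis-ready table of subject visits.

    ``frame`` holds one row per visit with the demographic columns, one
    column per test score and one column per morphometric feature.
    ``truth`` is only populated for synthetic data (noise-free scores and
    the generating cohort) and is consumed by
    :func:`sfascreen.synthetic_data.planted_truth`.
    """

    frame: pd.DataFrame
    feature_names: list[str]
    provenance: str = "real"
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("subject_id", "age", "cohort") if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame lacks mandatory columns {missing}")
        absent = [f for f in self.feature_names if f not in self.frame.columns]
        if absent:
            raise SchemaError(f"feature columns missing from frame: {absent[:5]}")
        bad = set(self.frame["cohort"].dropna()) - set(COHORTS)
        if bad:
            raise ValidationError(f"cohort labels outside {COHORTS}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def score_names(self) -> list[str]:
        return [t for t in TESTS if t in self.frame.columns]

    @property
    def subject_ids(self) -> set[str]:
        return set(self.frame["subject_id"].astype(str))

    def cohort_frame(self, cohort: str) -> pd.DataFrame:
        if cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {cohort!r}")
        return self.frame[self.frame["cohort"] == cohort]

    def record(self, i: int) -> SubjectRecord:
        row = self.frame.iloc[i]
        scores = {t: float(row[t]) for t in self.score_names if pd.notna(row[t])}
        return SubjectRecord(
            subject_id=str(row["subject_id"]),
            visit_index=int(row.get("visit_index", 1)),
            age=float(row["age"]),
            sex=row.get("sex") if pd.notna(row.get("sex")) else None,
            education=float(row["education"]) if pd.notna(row.get("education")) else None,
            cohort=str(row["cohort"]),
            features=row[self.feature_names].astype(float),
            scores=scores,
        )

    def iter_records(self) -> Iterator[SubjectRecord]:
        for i in range(len(self)):
            yield self.record(i)

    def select_rows(self, mask) -> "Dataset":
        sub = self.frame.loc[mask].reset_index(drop=True)
        truth = None
        if self.truth is not None:
            truth = self.truth.loc[mask].reset_index(drop=True)
        return replace(self, frame=sub, truth=truth)


class FilterResult(NamedTuple):
    dataset: Dataset
    report: dict[str, int]


# ---------------------------------------------------------------------------
# Subject tables
# ---------------------------------------------------------------------------


def _resolve_schema(schema) -> dict:
    if schema is None:
        schema = {}
    elif isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh) or {}
    elif not isinstance(schema, Mapping):
        raise SchemaError("schema must be a mapping or a path to a YAML file")
    out = {
        "columns": dict(schema.get("columns", {})),
        "scores": dict(schema.get("scores", {})),
        "features": schema.get("features"),
        "cohort_aliases": {
            **DEFAULT_COHORT_ALIASES,
            **{str(k).upper(): v for k, v in dict(schema.get("cohort_aliases", {})).items()},
        },
    }
    return out


def load_subject_table(path, schema=None, sep: str = ",") -> Dataset:
    """Read a delimited per-visit subject table into a validated Dataset.

    Parameters
    ----------
    path:
        CSV/TSV file, one row per visit.
    schema:
        Optional column-mapping config (mapping or YAML path) with keys
        ``columns`` (canonical demographic name -> source column),
        ``scores`` (test name -> source column), ``features`` (canonical
        feature name -> source column, or a list of source columns) and
        ``cohort_aliases``.  With no schema, canonical column names are
        expected and feature columns are auto-detected from the registry.

    Raises
    ------
    SchemaError
        if a mandatory column (id, age, cohort, >=1 score, >=1 feature)
        cannot be located.
    InputError
        if the file is empty.
    ValidationError
        if a cohort label is unknown or a value violates its bounds; the
        offending row is named.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty subject table: {path}") from None
    if raw.empty:
        raise InputError(f"subject table has no rows: {path}")

    sch = _resolve_schema(schema)
    colmap = sch["columns"]

    def source(canonical: str) -> str | None:
        src = colmap.get(canonical, canonical)
        return src if src in raw.columns else None

    for mandatory in ("subject_id", "age", "cohort"):
        if source(mandatory) is None:
            raise SchemaError(f"mandatory column {mandatory!r} not found in {path.name}")

    score_map = sch["scores"] or {t: t for t in TESTS}
    score_map = {t: c for t, c in score_map.items() if c in raw.columns}
    if not score_map:
        raise SchemaError("no test-score column found (need at least one)")

    feat_spec = sch["features"]
    if feat_spec is None:
        registry = default_feature_names()
        feature_map = {f: f for f in registry if f in raw.columns}
    elif isinstance(feat_spec, Mapping):
        feature_map = {k: v for k, v in feat_spec.items() if v in raw.columns}
    else:  # list of source columns used verbatim as feature names
        feature_map = {c: c for c in feat_spec if c in raw.columns}
    if not feature_map:
        raise SchemaError("no morphometric feature column found (need at least one)")

    columns: dict[str, object] = {}
    columns["subject_id"] = raw[source("subject_id")].astype(str)
    columns["visit_index"] = (
        pd.to_numeric(raw[source("visit_index")], errors="coerce").astype("Int64")
        if source("visit_index")
        else 1
    )
    columns["age"] = pd.to_numeric(raw[source("age")], errors="coerce")
    columns["sex"] = raw[source("sex")].map(_normalise_sex) if source("sex") else pd.NA
    columns["education"] = (
        pd.to_numeric(raw[source("education")], errors="coerce") if source("education") else np.nan
    )

    aliases = sch["cohort_aliases"]
    labels = raw[source("cohort")].astype(str).str.strip()
    mapped = labels.str.upper().map(aliases)
    unknown = mapped.isna() & labels.notna()
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ValidationError(
            f"unknown cohort label {labels.iloc[row]!r} in row {row} of {path.name}; "
            f"known labels/aliases: {sorted(set(aliases))}"
        )
    columns["cohort"] = mapped.to_numpy()

    for test, col in score_map.items():
        columns[test] = pd.to_numeric(raw[col], errors="coerce")
    feature_names = list(feature_map)
    for feat, col in feature_map.items():
        columns[feat] = pd.to_numeric(raw[col], errors="coerce")
    frame = pd.DataFrame(columns)

    # Rows whose mandatory fields failed coercion are reported, then dropped.
    bad_rows = frame.index[frame["age"].isna() | (frame["subject_id"] == "nan")]
    if len(bad_rows):
        warnings.warn(
            f"{len(bad_rows)} row(s) failed type coercion of mandatory fields "
            f"and were dropped: rows {list(bad_rows[:10])}",
            stacklevel=2,
        )
        frame = frame.drop(index=bad_rows).reset_index(drop=True)

    _validate_bounds(frame, list(score_map), feature_names, path.name)
    return Dataset(frame=frame, feature_names=feature_names, provenance="real")


def _normalise_sex(value):
    if pd.isna(value):
        return pd.NA
    s = str(value).strip().upper()
    if s in ("F", "FEMALE", "W", "WOMAN"):
        return "F"
    if s in ("M", "MALE", "MAN"):
        return "M"
    return pd.NA


def _validate_bounds(frame: pd.DataFrame, scores: list[str], features: list[str], name: str) -> None:
    lo, hi = AGE_BOUNDS
    off = frame.index[(frame["age"] < lo) | (frame["age"] > hi)]
    if len(off):
        raise ValidationError(
            f"age {frame.loc[off[0], 'age']} in row {off[0]} of {name} outside [{lo}, {hi}]"
        )
    for test in scores:
        scale = SCALES[test]
        vals = frame[test]
        bad = frame.index[vals.notna() & ((vals < scale.min_score) | (vals > scale.max_score))]
        if len(bad):
            raise ValidationError(
                f"{test}={vals.loc[bad[0]]} in row {bad[0]} of {name} violates scale "
                f"bounds [{scale.min_score}, {scale.max_score}] "
                f"(ceiling {scale.max_score})"
            )
    for feat in features:
        vals = frame[feat]
        bad = frame.index[vals.notna() & (vals < 0)]
        if len(bad):
            raise ValidationError(
                f"feature {feat}={vals.loc[bad[0]]} in row {bad[0]} of {name} is negative"
            )


def write_subject_table(dataset: Dataset, path) -> Path:
    """Serialise a Dataset to CSV in the canonical column layout.

    The canonical layout is what :func:`load_subject_table` reads with no
    schema, so ``load(write(ds))`` round-trips cleanly.
    """
    path = Path(path)
    cols = [c for c in DEMOGRAPHIC_COLUMNS if c in dataset.frame.columns]
    cols += dataset.score_names + dataset.feature_names
    # %.17g round-trips IEEE doubles exactly
    dataset.frame[cols].to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# FreeSurfer stats files
# ---------------------------------------------------------------------------

#: aseg StructName (sans hemisphere prefix) -> canonical structure key.
_ASEG_NAME_MAP: dict[str, str] = {
    "Hippocampus": "hippocampus",
    "Amygdala": "amygdala",
    "Thalamus": "thalamus",
    "Thalamus-Proper": "thalamus",
    "Putamen": "putamen",
    "Caudate": "caudate",
    "Pallidum": "pallidum",
    "Accumbens-area": "accumbens",
    "Lateral-Ventricle": "lateral_ventricle",
    "Inf-Lat-Vent": "inferior_lateral_ventricle",
    "Cerebral-White-Matter": "cerebral_white_matter",
    "Cerebral-Cortex": "cerebral_cortex",
}

#: Midline structures appearing without a hemisphere prefix.
_ASEG_MIDLINE: dict[str, str] = {
    "Brain-Stem": "brainstem",
    "CSF": "csf",
    "3rd-Ventricle": "third_ventricle",
    "4th-Ventricle": "fourth_ventricle",
}


@dataclass
class RawVolumes:
    """Absolute morphometry (mm^3 / mm / mm^2) parsed from FreeSurfer stats.

    ``volumes[structure]`` maps hemisphere (``"left"``/``"right"`` or
    ``"single"`` for midline structures) to mm^3.
    """

    tiv: float
    volumes: dict[str, dict[str, float]]
    thickness: dict[str, dict[str, float]] = field(default_factory=dict)
    area: dict[str, dict[str, float]] = field(default_factory=dict)


def _stats_body(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split())
    return rows


def _find_measure(path: Path, token: str) -> float | None:
    for line in path.read_text().splitlines():
        if line.startswith("#") and "Measure" in line and token in line:
            parts = [p.strip() for p in line.lstrip("# ").split(",")]
            for part in reversed(parts):
                try:
                    return float(part.replace("mm^3", "").strip())
                except ValueError:
                    continue
    return None


def parse_freesurfer_stats(aseg_path, aparc_lh_path=None, aparc_rh_path=None) -> RawVolumes:
    """Parse FreeSurfer ``aseg.stats`` (and optionally ``?h.aparc.stats``).

    Returns absolute volumes per structure and hemisphere plus TIV;
    cortical parcellations are keyed by their Desikan-Killiany names and
    additionally carry mean thickness and surface area when the aparc
    files are given.

    Raises :class:`ParseError` when the TIV measure line is absent.
    A structure seen in only one hemisphere triggers a warning and a
    missing value on the other side.
    """
    aseg_path = Path(aseg_path)
    tiv = _find_measure(aseg_path, "EstimatedTotalIntraCranialVol")
    if tiv is None:
        raise ParseError(f"{aseg_path.name}: no 'Measure EstimatedTotalIntraCranialVol' line")

    volumes: dict[str, dict[str, float]] = {}
    for row in _stats_body(aseg_path):
        if len(row) < 5:
            continue
        name, vol = row[4], float(row[3])
        for hemi, prefix in (("left", "Left-"), ("right", "Right-")):
            if name.startswith(prefix):
                canonical = _ASEG_NAME_MAP.get(name[len(prefix):])
                if canonical:
                    volumes.setdefault(canonical, {})[hemi] = vol
                break
        else:
            canonical = _ASEG_MIDLINE.get(name)
            if canonical:
                volumes.setdefault(canonical, {})["single"] = vol

    thickness: dict[str, dict[str, float]] = {}
    area: dict[str, dict[str, float]] = {}
    for hemi, aparc in (("left", aparc_lh_path), ("right", aparc_rh_path)):
        if aparc is None:
            continue
        for row in _stats_body(Path(aparc)):
            if len(row) < 5 or row[0] not in DK_REGIONS:
                continue
            region = row[0]
            area.setdefault(region, {})[hemi] = float(row[2])
            volumes.setdefault(region, {})[hemi] = float(row[3])
            thickness.setdefault(region, {})[hemi] = float(row[4])

    for structure, hemis in volumes.items():
        if "single" not in hemis and len(hemis) == 1:
            missing = "right" if "left" in hemis else "left"
            warnings.warn(
                f"{structure}: volume present in one hemisphere only ({missing} missing)",
                stacklevel=2,
            )
    return RawVolumes(tiv=tiv, volumes=volumes, thickness=thickness, area=area)


def compute_relative_volumes(raw: RawVolumes) -> dict[str, float]:
    """Bilaterally averaged volumes as a percentage of TIV.

    For each bilateral structure the value is
    ``100 * ((left + right) / 2) / TIV``; midline/unpaired structures use
    their single volume.  Structures missing on both sides are omitted
    with a warning.  ``TIV <= 0`` raises :class:`DomainError`.
    """
    if raw.tiv <= 0:
        raise DomainError(f"TIV must be positive, got {raw.tiv}")
    if not raw.volumes:
        raise DomainError("no structures present")
    out: dict[str, float] = {}
    for structure, hemis in raw.volumes.items():
        if "single" in hemis:
            absolute = hemis["single"]
        else:
            vals = [hemis[h] for h in ("left", "right") if h in hemis and np.isfinite(hemis[h])]
            if not vals:
                warnings.warn(f"{structure}: both hemispheres missing; omitted", stacklevel=2)
                continue
            absolute = float(np.mean(vals))
        out[f"vol_{structure}"] = 100.0 * absolute / raw.tiv
    return out


def build_feature_vector(raw: RawVolumes) -> pd.Series:
    """Full VBM+SBM feature vector for one subject.

    Volumes become % of TIV; thickness (mm) and surface area (mm^2) are
    bilaterally averaged and left in their native units (they are z-scored
    at model-fit time anyway).  Absent registry entries are NaN.
    """
    values = dict(compute_relative_volumes(raw))
    for prefix, table in (("thick_", raw.thickness), ("area_", raw.area)):
        for region, hemis in table.items():
            vals = [v for v in hemis.values() if np.isfinite(v)]
            if vals:
                values[f"{prefix}{region}"] = float(np.mean(vals))
    registry = default_feature_names()
    return pd.Series({f: values.get(f, np.nan) for f in registry}, index=registry, dtype=float)


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------


def apply_cohort_filters(dataset: Dataset, converter_policy: str = "drop") -> FilterResult:
    """Apply the study's inclusion filters; total (never raises).

    * records whose features are all missing are treated as segmentation
      failures and dropped;
    * with ``converter_policy="drop"``, every record of any subject that
      appears under more than one cohort label is removed (diagnostic
      converters must not contaminate the cohorts).

    Returns the filtered dataset plus a per-reason count report; the
    filtered size and the report counts always sum to the input size.
    """
    if converter_policy not in ("drop", "keep"):
        raise ValidationError(f"converter_policy must be 'drop' or 'keep', got {converter_policy!r}")
    frame = dataset.frame
    seg_fail = frame[dataset.feature_names].isna().all(axis=1)
    report = {"segmentation_failure": int(seg_fail.sum()), "cohort_converter": 0}
    keep = ~seg_fail
    if converter_policy == "drop":
        remaining = frame[keep]
        n_labels = remaining.groupby("subject_id")["cohort"].nunique()
        converters = set(n_labels.index[n_labels > 1])
        conv_mask = keep & frame["subject_id"].isin(converters)
        report["cohort_converter"] = int(conv_mask.sum())
        keep &= ~conv_mask
    return FilterResult(dataset.select_rows(keep.to_numpy()), report)
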