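"""Cohort tables: reading, validation, filtering, summaries and the fatal-CVD classifier.

The unit of analysis is a subject observed from a baseline examination
(``entry_age``, at which the risk-factor profile is measured) until death or
administrative censoring (``exit_age``).  Events are deaths from circulatory
disease, identified from the ICD code on the death certificate (ICD-8 range
390-458, ICD-10 chapter I) or, for synthetic cohorts without ICD coding, from
an explicit ``cause_is_cvd`` flag.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SEX_LABELS = ("male", "female")

#: Baseline risk-factor columns a profile may carry.
PROFILE_COLUMNS = (
    "sex", "age", "smoking", "sbp", "glucose", "cholesterol",
    "diabetes", "fasting_hours",
)

#: Follow-up / outcome columns.
SURVIVAL_COLUMNS = (
    "entry_age", "exit_age", "event", "cause_code", "icd_revision", "cause_is_cvd",
)

ALL_COLUMNS = ("subject_id",) + PROFILE_COLUMNS + SURVIVAL_COLUMNS

_SEX_ALIASES = {
    "male": "male", "m": "male", "men": "male", "1": "male",
    "female": "female", "f": "female", "women": "female", "2": "female",
}

_TRUTHY = {"true", "t", "yes", "y", "1", "1.0"}
_FALSY = {"false", "f", "no", "n", "0", "0.0"}

_ICD8_RE = re.compile(r"^(\d{3})(?:\.\d+)?$")
_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class ClassificationError(ValueError):
    """An ICD code does not have recognisable syntax for its revision."""


@dataclass(frozen=True)
class RiskFactorProfile:
    """One person's baseline covariate vector.

    Continuous covariates are in clinical units: systolic blood pressure in
    mmHg, fasting plasma glucose and total cholesterol in mmol/L.  ``smoking``
    means current smoking of at least one cigarette per day; former smokers
    count as non-smokers.
    """

    sex: str
    age: float
    smoking: bool
    sbp: float
    glucose: float | None = None
    cholesterol: float | None = None
    diabetes: bool | None = None
    fasting_hours: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEX_LABELS:
            raise ValueError(f"sex must be one of {SEX_LABELS}, got {self.sex!r}")
        if not np.isfinite(self.age) or self.age < 16:
            raise ValueError(f"age must be >= 16 (study inclusion), got {self.age}")
        if not self.sbp > 0:
            raise ValueError(f"sbp must be > 0, got {self.sbp}")
        for name in ("glucose", "cholesterol"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when present, got {v}")
        if self.fasting_hours is not None and not self.fasting_hours >= 0:
            raise ValueError(f"fasting_hours must be >= 0, got {self.fasting_hours}")

    def as_dict(self) -> dict:
        return {
            "sex": self.sex, "age": self.age, "smoking": self.smoking,
            "sbp": self.sbp, "glucose": self.glucose,
            "cholesterol": self.cholesterol, "diabetes": self.diabetes,
            "fasting_hours": self.fasting_hours,
        }


@dataclass(frozen=True)
class SubjectRecord:
    """A risk-factor profile plus the follow-up interval and outcome."""

    profile: RiskFactorProfile
    entry_age: float
    exit_age: float
    event: bool
    cause_code: str | None = None
    icd_revision: int | None = None

    def __post_init__(self) -> None:
        if not self.exit_age > self.entry_age:
            raise ValueError(
                f"exit_age ({self.exit_age}) must exceed entry_age ({self.entry_age})"
            )
        if self.event and self.cause_code is not None:
            if not classify_cvd_death(self.cause_code, self.icd_revision):
                raise ValueError(
                    f"event=True but cause code {self.cause_code!r} is not a CVD code"
                )


@dataclass
class CohortTable:
    """An ordered cohort backed by a pandas DataFrame with canonical columns.

    ``df`` always carries every column in :data:`ALL_COLUMNS`; optional fields
    that are absent hold NaN/NA.  ``rejections`` is the per-row validation
    report from :func:`read_cohort` (empty for programmatically built tables).
    """

    df: pd.DataFrame
    provenance: str = ""
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "subject_id", "reason"])
    )

    def __post_init__(self) -> None:
        for col in ALL_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = pd.NA
        self.df = self.df[list(ALL_COLUMNS)].reset_index(drop=True)
        ids = self.df["subject_id"]
        if ids.notna().any() and ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate subject identifier: {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["event"].astype(bool).sum())

    def records(self) -> list[SubjectRecord]:
        """Materialize the table as typed records (validates every row)."""
        out = []
        for _, r in self.df.iterrows():
            prof = RiskFactorProfile(
                sex=r["sex"], age=float(r["age"]), smoking=bool(r["smoking"]),
                sbp=float(r["sbp"]),
                glucose=None if pd.isna(r["glucose"]) else float(r["glucose"]),
                cholesterol=None if pd.isna(r["cholesterol"]) else float(r["cholesterol"]),
                diabetes=None if pd.isna(r["diabetes"]) else bool(r["diabetes"]),
                fasting_hours=None if pd.isna(r["fasting_hours"]) else float(r["fasting_hours"]),
            )
            out.append(SubjectRecord(
                profile=prof,
                entry_age=float(r["entry_age"]),
                exit_age=float(r["exit_age"]),
                event=bool(r["event"]),
                cause_code=None if pd.isna(r["cause_code"]) else str(r["cause_code"]),
                icd_revision=None if pd.isna(r["icd_revision"]) else int(r["icd_revision"]),
            ))
        return out

    def config_hash(self) -> str:
        payload = self.df.to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def classify_cvd_death(code: str, revision: int | None) -> bool:
    """Return True iff ``code`` denotes a circulatory-system death.

    ICD-8: numeric stem 390-458.  ICD-10: chapter I (letter 'I' followed by
    00-99).  Classification uses the 3-character stem; subdivisions after a
    decimal point are ignored.  Unrecognised syntax raises
    :class:`ClassificationError` rather than silently returning False, and
    revision 9 (never used for this endpoint) is rejected explicitly.
    """
    if code is None or str(code).strip() == "":
        raise ClassificationError("empty ICD code")
    code = str(code).strip().upper()
    if revision == 8:
        m = _ICD8_RE.match(code)
        if not m:
            raise ClassificationError(f"not a valid ICD-8 code: {code!r}")
        return 390 <= int(m.group(1)) <= 458
    if revision == 10:
        m = _ICD10_RE.match(code)
        if not m:
            raise ClassificationError(f"not a valid ICD-10 code: {code!r}")
        return m.group(1) == "I"
    raise ClassificationError(f"unsupported ICD revision: {revision!r}")


def _parse_bool(v) -> bool | None:
    if pd.isna(v):
        return None
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"unparseable boolean: {v!r}")


def _load_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh) or {}
    if not isinstance(schema, Mapping):
        raise SchemaError("schema must be a mapping canonical-name -> file column")
    return dict(schema)


def read_cohort(
    path,
    schema: Mapping[str, str] | str | Path | None = None,
    delimiter: str = ",",
    provenance: str | None = None,
) -> CohortTable:
    """Read and validate a cohort CSV.

    ``schema`` maps canonical column names (see :data:`ALL_COLUMNS`) to the
    file's column names, for files with nonstandard headers; it may also be a
    path to a YAML file with that mapping.  Rows violating a type invariant
    (age < 16, exit_age <= entry_age, non-positive measurements, an event
    whose ICD code is non-circulatory, ...) are rejected and reported in the
    returned table's ``rejections`` frame; the valid rows survive.

    Raises :class:`SchemaError` if a required column (sex, age, smoking, sbp,
    exit_age, event) cannot be resolved.
    """
    mapping = _load_schema(schema)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    rename = {v: k for k, v in mapping.items() if v in raw.columns}
    for canonical, source in mapping.items():
        if source not in raw.columns:
            raise SchemaError(f"schema maps {canonical!r} to missing column {source!r}")
    raw = raw.rename(columns=rename)

    required = ("sex", "age", "smoking", "sbp", "exit_age", "event")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"required column(s) not resolvable: {missing}")

    rows, rejects = [], []
    for i, r in raw.iterrows():
        try:
            rec = _coerce_row(r)
        except (ValueError, ClassificationError) as exc:
            rejects.append({"row": i, "subject_id": r.get("subject_id", pd.NA),
                            "reason": str(exc)})
            continue
        rows.append(rec)

    df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
    rej = pd.DataFrame(rejects, columns=["row", "subject_id", "reason"])
    logger.info("read_cohort: %d rows read, %d accepted, %d rejected",
                len(raw), len(df), len(rej))
    table = CohortTable(df=df, provenance=provenance or str(path))
    table.rejections = rej
    return table


def _coerce_row(r: pd.Series) -> dict:
    def fnum(name, required=False):
        v = r.get(name, pd.NA)
        if pd.isna(v) or str(v).strip() == "":
            if required:
                raise ValueError(f"missing required value: {name}")
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            raise ValueError(f"unparseable numeric in {name}: {v!r}")

    sex_raw = str(r.get("sex", "")).strip().lower()
    if sex_raw not in _SEX_ALIASES:
        raise ValueError(f"unrecognised sex label: {r.get('sex')!r}")
    sex = _SEX_ALIASES[sex_raw]

    age = fnum("age", required=True)
    if age < 16:
        raise ValueError(f"age below study inclusion (16): {age}")
    sbp = fnum("sbp", required=True)
    if not sbp > 0:
        raise ValueError(f"non-positive sbp: {sbp}")
    glucose = fnum("glucose")
    cholesterol = fnum("cholesterol")
    for name, v in (("glucose", glucose), ("cholesterol", cholesterol)):
        if not np.isnan(v) and not v > 0:
            raise ValueError(f"non-positive {name}: {v}")
    fasting = fnum("fasting_hours")
    if not np.isnan(fasting) and fasting < 0:
        raise ValueError(f"negative fasting_hours: {fasting}")

    smoking = _parse_bool(r.get("smoking"))
    if smoking is None:
        raise ValueError("missing smoking status")
    event = _parse_bool(r.get("event"))
    if event is None:
        raise ValueError("missing event indicator")
    diabetes = _parse_bool(r.get("diabetes", pd.NA))
    cause_is_cvd = _parse_bool(r.get("cause_is_cvd", pd.NA))

    entry = fnum("entry_age")
    if np.isnan(entry):
        entry = age
    exit_age = fnum("exit_age", required=True)
    if not exit_age > entry:
        raise ValueError(f"exit_age ({exit_age}) <= entry_age ({entry})")

    code = r.get("cause_code", pd.NA)
    code = None if (pd.isna(code) or str(code).strip() == "") else str(code).strip()
    rev = fnum("icd_revision")
    rev = None if np.isnan(rev) else int(rev)
    if event:
        if code is not None:
            if not classify_cvd_death(code, rev):
                raise ValueError(f"event with non-CVD cause code {code!r}")
        elif cause_is_cvd is False:
            raise ValueError("event=True with cause_is_cvd=False")

    return {
        "subject_id": r.get("subject_id", pd.NA),
        "sex": sex, "age": age, "smoking": smoking, "sbp": sbp,
        "glucose": glucose, "cholesterol": cholesterol, "diabetes": diabetes,
        "fasting_hours": fasting, "entry_age": entry, "exit_age": exit_age,
        "event": event, "cause_code": code, "icd_revision": rev,
        "cause_is_cvd": cause_is_cvd if cause_is_cvd is not None else event,
    }


def write_cohort(table: CohortTable, path, delimiter: str = ",") -> None:
    """Write a cohort table to CSV with the canonical column layout."""
    table.df.to_csv(path, sep=delimiter, index=False)


def fasting_filter(table: CohortTable, min_hours: float) -> CohortTable:
    """Keep subjects with fasting time strictly greater than ``min_hours``.

    Subjects with unknown fasting time are excluded (a subject who cannot
    demonstrate >2 h since the last meal is treated as non-fasting).
    """
    if not min_hours > 0:
        raise ValueError("min_hours must be positive")
    fh = pd.to_numeric(table.df["fasting_hours"], errors="coerce")
    keep = fh > min_hours
    removed = int((~keep).sum())
    logger.info("fasting_filter(>%s h): removed %d of %d rows",
                min_hours, removed, len(table))
    return CohortTable(df=table.df[keep].reset_index(drop=True),
                       provenance=f"{table.provenance}|fasting>{min_hours}h")


def exclude_missing(table: CohortTable, covariates: Sequence[str]) -> CohortTable:
    """Listwise-complete table on the named covariates."""
    valid = set(PROFILE_COLUMNS) | set(SURVIVAL_COLUMNS)
    for c in covariates:
        if c not in valid:
            raise KeyError(f"unknown covariate: {c!r}")
    if not covariates:
        return table
    sub = table.df[list(covariates)]
    keep = sub.notna().all(axis=1)
    logger.info("exclude_missing(%s): removed %d of %d rows",
                list(covariates), int((~keep).sum()), len(table))
    return CohortTable(df=table.df[keep].reset_index(drop=True),
                       provenance=f"{table.provenance}|complete:{','.join(covariates)}")


def summarize(table: CohortTable) -> pd.DataFrame:
    """Per-sex baseline summary: n, events, means, smoking proportion.

    Strata absent from the table are flagged with a warning and reported with
    n = 0 and NaN statistics rather than dropped silently.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = table.df
    rows = {}
    for sex in SEX_LABELS:
        sub = df[df["sex"] == sex]
        if len(sub) == 0:
            logger.warning("summarize: empty stratum %r", sex)
            rows[sex] = {"n": 0, "events": np.nan, "age_mean": np.nan,
                         "sbp_mean": np.nan, "glucose_mean": np.nan,
                         "cholesterol_mean": np.nan, "smoking_prop": np.nan}
            continue
        rows[sex] = {
            "n": len(sub),
            "events": int(sub["event"].astype(bool).sum()),
            "age_mean": pd.to_numeric(sub["age"]).mean(),
            "sbp_mean": pd.to_numeric(sub["sbp"]).mean(),
            "glucose_mean": pd.to_numeric(sub["glucose"], errors="coerce").mean(),
            "cholesterol_mean": pd.to_numeric(sub["cholesterol"], errors="coerce").mean(),
            "smoking_prop": sub["smoking"].astype(bool).mean(),
        }
    return pd.DataFrame(rows).T.rename_axis("sex")
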