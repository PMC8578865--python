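"""Reading, validation and filtering of long-format clinical trial tables.

The pipeline consumes one long-format CSV per trial (one row per subject x
visit day) carrying the three depression scales (HAMD-24, QIDS-SR16, PHQ-9)
and the serum BDNF concentration in pg/ml, plus a separate healthy-control
table that carries BDNF only.  This module validates those tables against a
fixed visit schedule and instrument ranges, enforces the enrollment floors
(HAMD-24 >= 20, QIDS-SR16 >= 5), and builds per-analysis complete-case views:
each downstream analysis declares the variables and days it needs, and only
subjects with every requested cell present are retained for it.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed visit-day vocabulary shared by both trials.
VISIT_DAYS = (0, 4, 7, 14, 28)
TRIALS = ("trial1", "trial2")
ARMS = ("yueju", "escitalopram", "healthy_control")
PATIENT_ARMS = ("yueju", "escitalopram")

SCALE_COLUMNS = ("hamd24", "qids_sr16", "phq9")
#: Instrument maxima (HAMD-24 item sum; QIDS-SR16 and PHQ-9 self-report ranges).
SCALE_MAX = {"hamd24": 76, "qids_sr16": 27, "phq9": 27}
MEASURE_COLUMNS = SCALE_COLUMNS + ("bdnf_pg_ml",)
REQUIRED_COLUMNS = ("subject_id", "trial", "arm", "day") + MEASURE_COLUMNS
OPTIONAL_COLUMNS = ("age", "sex")

#: Tokens (case-insensitive, after stripping) read as a missing value.
MISSING_TOKENS = frozenset({"", "na", "nan"})


class SchemaError(ValueError):
    """A table violates the column schema or a field-level invariant."""


class IntegrityError(ValueError):
    """A table violates a dataset-level invariant (e.g. duplicate visits)."""


@dataclasses.dataclass
class LoadReport:
    """Summary of one table ingestion.

    ``missing`` counts absent cells per measurement column (including
    recognised missing tokens); ``coerced`` counts cells that held an
    unparseable token and were demoted to missing with a warning.
    """

    path: str
    n_rows: int
    n_subjects: int
    missing: dict[str, int] = dataclasses.field(default_factory=dict)
    coerced: dict[str, int] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"column": c, "missing": self.missing.get(c, 0), "coerced": self.coerced.get(c, 0)}
            for c in MEASURE_COLUMNS
        ]
        return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class EnrollmentCriteria:
    """Trial enrollment floors applied to the day-0 (baseline) visit."""

    min_hamd24: int = 20
    min_qids: int = 5
    min_age: int = 18
    max_age: int = 65

    def __post_init__(self) -> None:
        if self.min_hamd24 <= 0:
            raise ValueError("min_hamd24 must be positive")


@dataclasses.dataclass(frozen=True)
class Exclusion:
    subject_id: str
    reason: str


class TrialDataset:
    """A validated long-format table of subject x visit measurements.

    Wraps a :class:`pandas.DataFrame` with one row per (subject, day).
    Missing measurements are NaN.  Construction validates:

    * required columns present,
    * ``day`` in the fixed schedule vocabulary,
    * ``trial`` / ``arm`` values from their enums,
    * scale scores are non-negative integers within instrument maxima,
    * BDNF strictly positive where present,
    * (subject_id, day) pairs unique,
    * healthy-control rows carry no scale scores,
    * every patient has a day-0 row with HAMD-24 present.
    """

    schema_version = "1.0"

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.reset_index(drop=True)
        if validate:
            frame = _validate_frame(frame)
        self._frame = frame

    # ------------------------------------------------------------------ views
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying table (treat as read-only)."""
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids, in first-appearance order."""
        return list(dict.fromkeys(self._frame["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def arm_of(self, subject_id: str) -> str:
        rows = self._frame[self._frame["subject_id"] == subject_id]
        if rows.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return rows["arm"].iloc[0]

    def patients(self) -> "TrialDataset":
        return self._subset_rows(self._frame["arm"] != "healthy_control")

    def controls(self) -> "TrialDataset":
        return self._subset_rows(self._frame["arm"] == "healthy_control")

    def for_arm(self, arm: str) -> "TrialDataset":
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        return self._subset_rows(self._frame["arm"] == arm)

    def subset_subjects(self, subject_ids: Iterable[str]) -> "TrialDataset":
        keep = set(subject_ids)
        return self._subset_rows(self._frame["subject_id"].isin(keep))

    def _subset_rows(self, mask) -> "TrialDataset":
        return TrialDataset(self._frame[mask], validate=False)

    def value(self, subject_id: str, day: int, column: str) -> float:
        """One measurement; NaN when the cell (or the row) is absent."""
        f = self._frame
        rows = f[(f["subject_id"] == subject_id) & (f["day"] == day)]
        if rows.empty:
            return float("nan")
        return float(rows[column].iloc[0])

    def pivot(self, column: str, days: Sequence[int] | None = None) -> pd.DataFrame:
        """Subjects x days matrix for one measurement column (NaN = absent)."""
        if column not in MEASURE_COLUMNS:
            raise ValueError(f"unknown measurement column {column!r}")
        wide = self._frame.pivot(index="subject_id", columns="day", values=column)
        wide = wide.reindex(self.subjects)
        if days is not None:
            wide = wide.reindex(columns=list(days))
        return wide

    # ------------------------------------------------------------------- io
    def write_csv(self, path: str | Path) -> None:
        cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in self._frame.columns]
        out = self._frame[cols].copy()
        out.to_csv(path, index=False)


def _parse_numeric_column(raw: pd.Series, report: LoadReport, column: str) -> pd.Series:
    """Parse a string column to float, mapping missing tokens / garbage to NaN."""
    stripped = raw.astype(str).str.strip()
    is_missing_token = stripped.str.lower().isin(MISSING_TOKENS)

    def _to_float(tok: str) -> float:
        # float() is correctly rounded, so written tables re-read bit-exactly
        try:
            return float(tok)
        except ValueError:
            return float("nan")

    parsed = stripped.map(_to_float)
    parsed[is_missing_token] = np.nan
    coerced = parsed.isna() & ~is_missing_token
    n_coerced = int(coerced.sum())
    if n_coerced:
        report.coerced[column] = report.coerced.get(column, 0) + n_coerced
        for idx in np.flatnonzero(coerced.to_numpy())[:5]:
            msg = f"row {idx + 2}: unparseable {column} value {stripped.iloc[idx]!r} -> missing"
            report.warnings.append(msg)
            logger.warning("%s: %s", report.path, msg)
    report.missing[column] = int(parsed.isna().sum())
    return parsed.astype(float)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    frame = frame.copy()
    frame["subject_id"] = frame["subject_id"].astype(str)

    bad_trial = ~frame["trial"].isin(TRIALS)
    if bad_trial.any():
        raise SchemaError(f"unknown trial value {frame.loc[bad_trial, 'trial'].iloc[0]!r}")
    bad_arm = ~frame["arm"].isin(ARMS)
    if bad_arm.any():
        raise SchemaError(f"unknown arm value {frame.loc[bad_arm, 'arm'].iloc[0]!r}")

    day = pd.to_numeric(frame["day"], errors="coerce")
    if day.isna().any() or (day != day.astype(int)).any():
        raise SchemaError("day must be an integer")
    frame["day"] = day.astype(int)
    bad_day = ~frame["day"].isin(VISIT_DAYS)
    if bad_day.any():
        raise SchemaError(
            f"day {int(frame.loc[bad_day, 'day'].iloc[0])} outside schedule {VISIT_DAYS}"
        )

    dup = frame.duplicated(subset=["subject_id", "day"])
    if dup.any():
        sid = frame.loc[dup, "subject_id"].iloc[0]
        d = int(frame.loc[dup, "day"].iloc[0])
        raise IntegrityError(f"duplicate record for subject {sid!r}, day {d}")

    for col in MEASURE_COLUMNS:
        frame[col] = pd.to_numeric(frame[col], errors="coerce").astype(float)

    for col in SCALE_COLUMNS:
        vals = frame[col].dropna()
        if ((vals < 0) | (vals % 1 != 0)).any():
            raise SchemaError(f"{col} scores must be non-negative integers")
        if (vals > SCALE_MAX[col]).any():
            raise SchemaError(f"{col} exceeds instrument maximum {SCALE_MAX[col]}")

    bdnf = frame["bdnf_pg_ml"].dropna()
    if (bdnf <= 0).any():
        raise SchemaError("bdnf_pg_ml must be positive where present")

    is_control = frame["arm"] == "healthy_control"
    if is_control.any():
        scales_present = frame.loc[is_control, list(SCALE_COLUMNS)].notna()
        if scales_present.any().any():
            raise SchemaError("healthy_control records must not carry scale scores")

    patients = frame[~is_control]
    if not patients.empty:
        baseline = patients[patients["day"] == 0]
        have_baseline = set(baseline.loc[baseline["hamd24"].notna(), "subject_id"])
        missing = [s for s in dict.fromkeys(patients["subject_id"]) if s not in have_baseline]
        if missing:
            raise IntegrityError(
                f"subject {missing[0]!r} lacks a day-0 record with hamd24 present"
            )
    return frame


def read_trial_table(
    path: str | Path, expected_trial: str | None = None
) -> tuple[TrialDataset, LoadReport]:
    """Read and validate a long-format trial CSV.

    Unparseable numeric cells become missing values and are counted in the
    returned :class:`LoadReport`; recognised missing tokens (empty cell,
    ``NA``, ``NaN``, case-insensitive) are silently missing.  Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    report = LoadReport(path=str(path), n_rows=len(raw), n_subjects=0)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    for col in MEASURE_COLUMNS + ("age",):
        if col in raw.columns:
            raw[col] = _parse_numeric_column(raw[col], report, col)
    dataset = TrialDataset(raw)
    report.n_subjects = dataset.n_subjects
    if expected_trial is not None:
        pat = dataset.frame[dataset.frame["arm"] != "healthy_control"]
        wrong = pat[pat["trial"] != expected_trial]
        if not wrong.empty:
            raise SchemaError(
                f"expected trial {expected_trial!r}, found {wrong['trial'].iloc[0]!r}"
            )
    logger.info(
        "%s: %d rows, %d subjects, %d warnings",
        path, report.n_rows, report.n_subjects, report.n_warnings,
    )
    return dataset, report


def read_control_table(path: str | Path, trial: str = "trial1") -> tuple[TrialDataset, LoadReport]:
    """Read a healthy-control CSV (columns: subject_id, arm, bdnf_pg_ml).

    Control records are assigned day 0 and the given trial label so they fit
    the shared record schema.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    report = LoadReport(path=str(path), n_rows=len(raw), n_subjects=0)
    for col in ("subject_id", "arm", "bdnf_pg_ml"):
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    raw["bdnf_pg_ml"] = _parse_numeric_column(raw["bdnf_pg_ml"], report, "bdnf_pg_ml")
    if (raw["arm"] != "healthy_control").any():
        raise SchemaError("control table rows must have arm=healthy_control")
    frame = pd.DataFrame(
        {
            "subject_id": raw["subject_id"],
            "trial": trial,
            "arm": "healthy_control",
            "day": 0,
            "hamd24": np.nan,
            "qids_sr16": np.nan,
            "phq9": np.nan,
            "bdnf_pg_ml": raw["bdnf_pg_ml"],
        }
    )
    dataset = TrialDataset(frame)
    report.n_subjects = dataset.n_subjects
    return dataset, report


def apply_enrollment(
    dataset: TrialDataset, criteria: EnrollmentCriteria = EnrollmentCriteria()
) -> tuple[TrialDataset, list[Exclusion]]:
    """Drop (whole) subjects whose baseline visit violates the enrollment floors.

    A subject is excluded in full when the day-0 HAMD-24 or QIDS-SR16 falls
    below its floor, or (when an ``age`` column is present) the age is outside
    the allowed range.  Floors are inclusive; a criterion measured as missing
    at baseline is not grounds for exclusion.  Healthy controls pass through.
    """
    frame = dataset.frame
    exclusions: list[Exclusion] = []
    baseline = frame[(frame["day"] == 0) & (frame["arm"] != "healthy_control")]
    for _, row in baseline.iterrows():
        sid = row["subject_id"]
        hamd = row["hamd24"]
        if pd.notna(hamd) and hamd < criteria.min_hamd24:
            exclusions.append(Exclusion(sid, f"hamd24 < {criteria.min_hamd24}"))
            continue
        qids = row["qids_sr16"]
        if pd.notna(qids) and qids < criteria.min_qids:
            exclusions.append(Exclusion(sid, f"qids_sr16 < {criteria.min_qids}"))
            continue
        if "age" in frame.columns:
            age = row.get("age", np.nan)
            if pd.notna(age) and not (criteria.min_age <= age <= criteria.max_age):
                exclusions.append(
                    Exclusion(sid, f"age outside {criteria.min_age}-{criteria.max_age}")
                )
    excluded = {e.subject_id for e in exclusions}
    kept = dataset._subset_rows(~frame["subject_id"].isin(excluded))
    for e in exclusions:
        logger.info("excluded %s: %s", e.subject_id, e.reason)
    return kept, exclusions


def complete_cases(
    dataset: TrialDataset, variables: Sequence[str], days: Sequence[int]
) -> TrialDataset:
    """Retain only subjects with every requested variable on every requested day."""
    if not variables or not days:
        raise ValueError("variables and days must be non-empty")
    for v in variables:
        if v not in MEASURE_COLUMNS:
            raise ValueError(f"unknown variable {v!r}")
    ok = pd.Series(True, index=dataset.subjects)
    for v in variables:
        wide = dataset.pivot(v, days)
        ok &= wide.notna().all(axis=1)
    return dataset.subset_subjects(ok.index[ok])


def exclusions_to_frame(exclusions: Sequence[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": e.subject_id, "reason": e.reason} for e in exclusions],
        columns=["subject_id", "reason"],
    )
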