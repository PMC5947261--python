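"""Tabular data model for vibrissa stable-isotope studies.

Three delimited-text tables drive the analysis:

* an isotope table — one row per vibrissa sample with its δ13C (vs V-PDB)
  and δ15N (vs atmospheric air) values in per mil (‰),
* a weight table — paired consecutive-morning weight records with age, sex,
  recent rainfall and group size covariates,
* a census table — daily head counts per social group.

All readers are strict on schema (a missing column is an error naming the
column) and row-validated; isotope values far outside anything biologically
plausible are treated as unit errors and dropped with a warning rather than
poisoning downstream covariance estimates.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeSample",
    "WeightObservation",
    "GroupCensus",
    "SchemaError",
    "RowValidationError",
    "delta_from_ratio",
    "read_isotope_table",
    "write_isotope_table",
    "read_weight_table",
    "read_census_table",
    "write_census_table",
    "filter_min_samples",
    "samples_to_frame",
]

# Plausibility windows (per mil) for animal keratin; values beyond these are
# almost certainly unit or transcription errors, not unusual ecology.
D13C_RANGE = (-60.0, 20.0)
D15N_RANGE = (-10.0, 40.0)

ISOTOPE_COLUMNS = ["sample_id", "individual_id", "group_id", "date", "d13C", "d15N"]
WEIGHT_COLUMNS = [
    "individual_id",
    "group_id",
    "date",
    "weight_first_g",
    "weight_second_g",
    "age_years",
    "sex",
    "rainfall_60d_mm",
    "group_size",
]
CENSUS_COLUMNS = ["group_id", "date", "n_members"]


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class RowValidationError(ValueError):
    """A row violates a field invariant; the message carries the row number."""


@dataclass(frozen=True)
class IsotopeSample:
    """One vibrissa measurement in (δ13C, δ15N) space."""

    sample_id: str
    individual_id: str
    group_id: str
    collection_date: datetime.date
    d13C: float
    d15N: float


@dataclass(frozen=True)
class WeightObservation:
    """Paired consecutive-morning weights with body-condition covariates."""

    individual_id: str
    group_id: str
    date: datetime.date
    weight_first_g: float
    weight_second_g: float | None
    age_years: float
    sex: str
    rainfall_60d_mm: float
    group_size_first_morning: int


@dataclass(frozen=True)
class GroupCensus:
    """Head count of one social group on one calendar day."""

    group_id: str
    date: datetime.date
    n_members: int


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert a heavy/light isotope ratio to δ notation in per mil.

    δX = ((R_sample / R_standard) − 1) × 1000, with R_standard the
    international reference ratio (V-PDB for carbon, air for nitrogen).
    """
    r_sample = float(r_sample)
    r_standard = float(r_standard)
    if r_standard <= 0:
        raise ValueError(f"reference ratio must be positive, got {r_standard}")
    if r_sample < 0:
        raise ValueError(f"sample ratio must be non-negative, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_date(value, row: int, path) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowValidationError(f"{path}: row {row}: unparseable date {value!r}") from exc


def _parse_float(value, row: int, path, column: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise RowValidationError(
            f"{path}: row {row}: unparseable {column} value {value!r}"
        ) from exc
    if not np.isfinite(out):
        raise RowValidationError(f"{path}: row {row}: non-finite {column} value {value!r}")
    return out


def read_isotope_table(path) -> list[IsotopeSample]:
    """Read the isotope CSV, validate every row, and return samples.

    Rows whose δ values fall outside the plausibility windows are dropped
    with a warning (unit-error guard); schema problems and unparseable
    values raise.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty (no header row)") from exc
    _require_columns(frame, ISOTOPE_COLUMNS, path)

    samples: list[IsotopeSample] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    for row_number, rec in enumerate(frame.itertuples(index=False), start=2):
        d13c = _parse_float(rec.d13C, row_number, path, "d13C")
        d15n = _parse_float(rec.d15N, row_number, path, "d15N")
        if not (D13C_RANGE[0] <= d13c <= D13C_RANGE[1] and D15N_RANGE[0] <= d15n <= D15N_RANGE[1]):
            n_dropped += 1
            continue
        key = (str(rec.individual_id), str(rec.sample_id))
        if key in seen:
            raise RowValidationError(
                f"{path}: row {row_number}: duplicate (individual_id, sample_id) {key}"
            )
        seen.add(key)
        samples.append(
            IsotopeSample(
                sample_id=str(rec.sample_id),
                individual_id=str(rec.individual_id),
                group_id=str(rec.group_id),
                collection_date=_parse_date(rec.date, row_number, path),
                d13C=d13c,
                d15N=d15n,
            )
        )
    if n_dropped:
        warnings.warn(
            f"{path}: dropped {n_dropped} row(s) with isotope values outside "
            f"δ13C {D13C_RANGE} / δ15N {D15N_RANGE} ‰",
            stacklevel=2,
        )
    return samples


def samples_to_frame(samples: Iterable[IsotopeSample]) -> pd.DataFrame:
    """Flatten samples into the canonical isotope-table DataFrame."""
    rows = [
        {
            "sample_id": s.sample_id,
            "individual_id": s.individual_id,
            "group_id": s.group_id,
            "date": s.collection_date.isoformat(),
            "d13C": s.d13C,
            "d15N": s.d15N,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=ISOTOPE_COLUMNS)


def write_isotope_table(samples: Iterable[IsotopeSample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.6f")


def read_weight_table(path) -> list[WeightObservation]:
    """Read paired-morning weight records; a blank second weight is kept as None."""
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty (no header row)") from exc
    _require_columns(frame, WEIGHT_COLUMNS, path)

    out: list[WeightObservation] = []
    for row_number, rec in enumerate(frame.itertuples(index=False), start=2):
        w1 = _parse_float(rec.weight_first_g, row_number, path, "weight_first_g")
        w2_raw = rec.weight_second_g
        w2 = None
        if w2_raw is not None and str(w2_raw).strip() not in ("", "nan", "NA"):
            w2 = _parse_float(w2_raw, row_number, path, "weight_second_g")
            if w2 <= 0:
                raise RowValidationError(f"{path}: row {row_number}: non-positive weight")
        age = _parse_float(rec.age_years, row_number, path, "age_years")
        size = int(_parse_float(rec.group_size, row_number, path, "group_size"))
        sex = str(rec.sex).strip().lower()
        if w1 <= 0:
            raise RowValidationError(f"{path}: row {row_number}: non-positive weight")
        if age < 0:
            raise RowValidationError(f"{path}: row {row_number}: negative age")
        if size < 1:
            raise RowValidationError(f"{path}: row {row_number}: group_size < 1")
        if sex not in ("female", "male"):
            raise RowValidationError(f"{path}: row {row_number}: sex must be female/male")
        out.append(
            WeightObservation(
                individual_id=str(rec.individual_id),
                group_id=str(rec.group_id),
                date=_parse_date(rec.date, row_number, path),
                weight_first_g=w1,
                weight_second_g=w2,
                age_years=age,
                sex=sex,
                rainfall_60d_mm=_parse_float(
                    rec.rainfall_60d_mm, row_number, path, "rainfall_60d_mm"
                ),
                group_size_first_morning=size,
            )
        )
    return out


def read_census_table(path) -> list[GroupCensus]:
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty (no header row)") from exc
    _require_columns(frame, CENSUS_COLUMNS, path)

    out: list[GroupCensus] = []
    seen: set[tuple[str, datetime.date]] = set()
    for row_number, rec in enumerate(frame.itertuples(index=False), start=2):
        n = int(_parse_float(rec.n_members, row_number, path, "n_members"))
        if n < 1:
            raise RowValidationError(f"{path}: row {row_number}: n_members < 1")
        date = _parse_date(rec.date, row_number, path)
        key = (str(rec.group_id), date)
        if key in seen:
            raise RowValidationError(
                f"{path}: row {row_number}: duplicate census for {key}"
            )
        seen.add(key)
        out.append(GroupCensus(group_id=str(rec.group_id), date=date, n_members=n))
    return out


def write_census_table(census: Iterable[GroupCensus], path) -> None:
    rows = [
        {"group_id": c.group_id, "date": c.date.isoformat(), "n_members": c.n_members}
        for c in census
    ]
    pd.DataFrame(rows, columns=CENSUS_COLUMNS).to_csv(path, index=False)


def filter_min_samples(
    samples: Sequence[IsotopeSample], k: int = 4
) -> list[IsotopeSample]:
    """Keep only samples of individuals with at least ``k`` samples.

    Repeated measurements are what make an individual's niche ellipse
    estimable; the default of four samples per individual is the minimum
    for a meaningfully corrected bivariate ellipse.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: dict[str, int] = {}
    for s in samples:
        counts[s.individual_id] = counts.get(s.individual_id, 0) + 1
    return [s for s in samples if counts[s.individual_id] >= k]


def modal_group(samples: Sequence[IsotopeSample]) -> str:
    """Most frequent group id among an individual's samples (ties: lexicographic)."""
    if not samples:
        raise ValueError("no samples")
    counts: dict[str, int] = {}
    for s in samples:
        counts[s.group_id] = counts.get(s.group_id, 0) + 1
    return max(sorted(counts), key=counts.get)
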