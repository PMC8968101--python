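"""Cohort table handling.

The study cohort is a 16-animal table of healthy domestic pigs: per-animal
covariates (gender, age, heart rate, systolic blood pressure, hematocrit,
body weight) together with the two measured endpoints, the myocardial
extracellular volume fraction (ECV, dimensionless) and the cardiomyocyte
breadth (CmyB, the shorter diameter of the oval cell cross-section, in um).
Two animals have no endpoint data: one died during imaging and one lost the
enhanced scan, so 14 of 16 animals enter the ECV/CmyB analysis while
covariates such as body weight remain available for all 16.

The packaged fixture ``data/table1.csv`` carries the full per-animal table;
missing endpoints are empty CSV cells, never sentinel numbers.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CohortParseError, CohortValidationError, InsufficientDataError

STATUSES = ("analyzed", "died", "scan_failed")

CSV_COLUMNS = (
    "animal_id",
    "gender",
    "age_weeks",
    "heart_rate",
    "systolic_bp",
    "hematocrit",
    "body_weight_kg",
    "ecv",
    "cmyb_mean_um",
    "cmyb_sd_um",
    "status",
)

# CSV column -> AnimalRecord attribute (identity except for the unit-suffixed ones)
_COL_TO_ATTR = {
    "body_weight_kg": "body_weight",
    "cmyb_mean_um": "cmyb_mean",
    "cmyb_sd_um": "cmyb_sd",
}


@dataclass(frozen=True)
class AnimalRecord:
    """One cohort row: covariates plus (optionally missing) endpoints."""

    animal_id: int
    gender: str
    age_weeks: int
    heart_rate: float
    systolic_bp: float
    hematocrit: float | None
    body_weight: float  # kg
    ecv: float | None  # fraction in (0, 1)
    cmyb_mean: float | None  # um
    cmyb_sd: float | None  # um
    status: str = "analyzed"

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise CohortValidationError(
                f"animal {self.animal_id}: gender must be 'M' or 'F', got {self.gender!r}"
            )
        if self.status not in STATUSES:
            raise CohortValidationError(
                f"animal {self.animal_id}: unknown status {self.status!r}"
            )
        if self.hematocrit is not None and not (0.0 < self.hematocrit < 1.0):
            raise CohortValidationError(
                f"animal {self.animal_id}: hematocrit {self.hematocrit} outside (0, 1)"
            )
        if self.ecv is not None and not (0.0 < self.ecv < 1.0):
            raise CohortValidationError(
                f"animal {self.animal_id}: ecv {self.ecv} outside (0, 1)"
            )
        for name in ("cmyb_mean", "cmyb_sd"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise CohortValidationError(
                    f"animal {self.animal_id}: {name} must be positive, got {value}"
                )
        has_endpoints = self.ecv is not None and self.cmyb_mean is not None
        if (self.status == "analyzed") != has_endpoints:
            raise CohortValidationError(
                f"animal {self.animal_id}: status 'analyzed' requires both ecv and "
                f"cmyb_mean present, and vice versa"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- sample SD (n-1 denominator) of one cohort variable."""

    variable_name: str
    n: int
    mean: float
    sd: float


def _parse_cell(text: str, column: str, row: int, kind: type) -> float | int | None:
    text = text.strip()
    if text == "":
        return None
    try:
        return kind(text)
    except ValueError as exc:
        raise CohortParseError(
            f"row {row}, column {column!r}: cannot parse {text!r}"
        ) from exc


def load_cohort(path: str | Path) -> list[AnimalRecord]:
    """Read a cohort CSV into validated :class:`AnimalRecord` objects.

    Missing cells become ``None``. Raises :class:`CohortParseError` for
    malformed numbers (naming row and column) and
    :class:`CohortValidationError` for out-of-range values.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CSV_COLUMNS:
            raise CohortParseError(
                f"{path}: header {reader.fieldnames} does not match the declared "
                f"schema {list(CSV_COLUMNS)}"
            )
        records: list[AnimalRecord] = []
        for i, row in enumerate(reader, start=2):  # CSV line number
            kwargs: dict = {}
            for col in CSV_COLUMNS:
                attr = _COL_TO_ATTR.get(col, col)
                raw = row[col] or ""
                if col in ("gender", "status"):
                    kwargs[attr] = raw.strip()
                elif col in ("animal_id", "age_weeks"):
                    value = _parse_cell(raw, col, i, int)
                    if value is None:
                        raise CohortParseError(f"row {i}, column {col!r}: cell is empty")
                    kwargs[attr] = value
                else:
                    kwargs[attr] = _parse_cell(raw, col, i, float)
            for required in ("heart_rate", "systolic_bp", "body_weight"):
                if kwargs[required] is None:
                    raise CohortParseError(
                        f"row {i}: required column {required!r} is empty"
                    )
            records.append(AnimalRecord(**kwargs))
    return records


def write_cohort(records: Iterable[AnimalRecord], path: str | Path) -> None:
    """Write records back to CSV with the canonical header; None -> empty cell."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row = []
            for col in CSV_COLUMNS:
                value = getattr(rec, _COL_TO_ATTR.get(col, col))
                row.append("" if value is None else value)
            writer.writerow(row)


def packaged_table1_path() -> Path:
    """Path of the packaged per-animal cohort fixture."""
    return Path(resources.files("myoecv").joinpath("data/table1.csv"))


def load_table1() -> list[AnimalRecord]:
    """Load the packaged 16-animal cohort fixture."""
    return load_cohort(packaged_table1_path())


def analyzable_subset(records: Sequence[AnimalRecord]) -> list[AnimalRecord]:
    """Records with status ``analyzed`` (both endpoints present), order kept."""
    return [r for r in records if r.status == "analyzed"]


_FIELD_NAMES = {f.name for f in dc_fields(AnimalRecord)}


def summarize(records: Sequence[AnimalRecord], variable: str) -> CohortSummary:
    """Mean and sample SD (n-1) of one numeric variable over non-missing rows."""
    if variable not in _FIELD_NAMES:
        raise KeyError(f"unknown variable {variable!r}")
    values = [getattr(r, variable) for r in records]
    values = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=float,
    )
    if values.size < 2:
        raise InsufficientDataError(
            f"need >=2 non-missing values of {variable!r}, got {values.size}"
        )
    return CohortSummary(
        variable_name=variable,
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
    )
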