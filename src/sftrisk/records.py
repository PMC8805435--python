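"""Per-patient records and the cohort CSV schema.

A :class:`PatientRecord` carries the raw clinicopathological covariates that
feed the risk models (age, tumor size, mitotic frequency, Ki-67 labeling
index, necrosis extent, dedifferentiation) together with the follow-up /
metastasis data needed for metastasis-free-survival analysis.

The on-disk interchange format is a plain CSV with one header row and the
exact column set in :data:`COHORT_COLUMNS`. Booleans are written as 0/1 and
``time_to_metastasis_months`` is left blank for patients without metastasis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

SEXES = ("male", "female")
LOCATIONS = ("intrathoracic", "intra_abdominal", "cns", "other")

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "location",
    "tumor_size_cm",
    "mitoses_per_mm2",
    "ki67_li_pct",
    "necrosis_pct",
    "dedifferentiation",
    "follow_up_months",
    "metastasis",
    "time_to_metastasis_months",
)


class ValidationError(ValueError):
    """Raised when an input value is outside its clinical domain."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject's covariates plus follow-up and event data.

    Units: ``age`` in years, ``tumor_size_cm`` in centimetres,
    ``mitoses_per_mm2`` per square millimetre, ``ki67_li_pct`` and
    ``necrosis_pct`` in percent of tumor nuclei / tumor area, times in
    months from surgical resection or biopsy.
    """

    patient_id: str
    age: float
    sex: str
    location: str
    tumor_size_cm: float
    mitoses_per_mm2: float
    ki67_li_pct: float
    necrosis_pct: float
    dedifferentiation: bool
    follow_up_months: float
    metastasis: bool
    time_to_metastasis_months: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be non-negative, got {self.age}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.location not in LOCATIONS:
            raise ValidationError(
                f"location must be one of {LOCATIONS}, got {self.location!r}"
            )
        if not self.tumor_size_cm > 0:
            raise ValidationError(
                f"tumor_size_cm must be positive, got {self.tumor_size_cm}"
            )
        if self.mitoses_per_mm2 < 0:
            raise ValidationError(
                f"mitoses_per_mm2 must be non-negative, got {self.mitoses_per_mm2}"
            )
        if not 0 <= self.ki67_li_pct <= 100:
            raise ValidationError(
                f"ki67_li_pct must be in [0, 100], got {self.ki67_li_pct}"
            )
        if not 0 <= self.necrosis_pct <= 100:
            raise ValidationError(
                f"necrosis_pct must be in [0, 100], got {self.necrosis_pct}"
            )
        if self.follow_up_months < 0:
            raise ValidationError(
                f"follow_up_months must be non-negative, got {self.follow_up_months}"
            )
        if self.metastasis:
            if self.time_to_metastasis_months is None:
                raise ValidationError(
                    f"patient {self.patient_id}: metastasis recorded without "
                    "time_to_metastasis_months"
                )
            if self.time_to_metastasis_months > self.follow_up_months:
                raise ValidationError(
                    f"patient {self.patient_id}: time_to_metastasis_months "
                    f"({self.time_to_metastasis_months}) exceeds follow-up "
                    f"({self.follow_up_months})"
                )
        elif self.time_to_metastasis_months is not None:
            raise ValidationError(
                f"patient {self.patient_id}: time_to_metastasis_months given "
                "but metastasis is false"
            )


def cohort_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate records into the canonical cohort CSV column order."""
    rows = []
    for rec in records:
        row = asdict(rec)
        row["dedifferentiation"] = int(rec.dedifferentiation)
        row["metastasis"] = int(rec.metastasis)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def dataframe_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    extra = set(df.columns) - set(COHORT_COLUMNS)
    if extra:
        raise ValidationError(f"cohort table has unknown columns: {sorted(extra)}")
    records = []
    for _, row in df.iterrows():
        metastasis = bool(int(row["metastasis"]))
        ttm = row["time_to_metastasis_months"]
        ttm = None if pd.isna(ttm) else float(ttm)
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                location=str(row["location"]),
                tumor_size_cm=float(row["tumor_size_cm"]),
                mitoses_per_mm2=float(row["mitoses_per_mm2"]),
                ki67_li_pct=float(row["ki67_li_pct"]),
                necrosis_pct=float(row["necrosis_pct"]),
                dedifferentiation=bool(int(row["dedifferentiation"])),
                follow_up_months=float(row["follow_up_months"]),
                metastasis=metastasis,
                time_to_metastasis_months=ttm,
            )
        )
    return records


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; every row becomes a PatientRecord."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str, "location": str})
    return dataframe_to_cohort(df)


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    cohort_to_dataframe(list(records)).to_csv(path, index=False)
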