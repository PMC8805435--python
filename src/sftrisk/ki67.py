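"""Ki-67 labeling index from labeled-nuclei counts and hot-spot selection.

The quantifier works downstream of image analysis: each candidate microscopic
field contributes a count of Ki-67-positive and Ki-67-negative tumor nuclei
(nuclear staining only). The labeling index (LI) of a field is its positive
fraction in percent; the "hot spot" is the eligible field with the highest
LI, and the hot-spot LI is what the risk models bin into the 0/1/2 Ki-67
score. Segmentation, stain classification and anything pixel-level are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import ValidationError
from .scoring import DEFAULT_BINS, ScoreBins, score_ki67

#: Fields with fewer tumor nuclei than this are ineligible as hot spots.
DEFAULT_MIN_NUCLEI = 500

FIELD_COLUMNS = ("field_id", "positive", "negative")


@dataclass(frozen=True)
class NucleiField:
    """Positive / negative Ki-67 nucleus counts for one candidate field."""

    field_id: str
    positive: int
    negative: int

    def __post_init__(self) -> None:
        if self.positive < 0 or self.negative < 0:
            raise ValidationError(
                f"field {self.field_id}: nucleus counts must be non-negative"
            )

    @property
    def total(self) -> int:
        return self.positive + self.negative


def field_li(field: NucleiField) -> float:
    """Labeling index of one field: 100 * positive / (positive + negative)."""
    if field.total < 1:
        raise ValidationError(f"field {field.field_id}: no nuclei counted")
    return 100.0 * field.positive / field.total


def select_hotspot(
    fields: Iterable[NucleiField], min_nuclei: int = DEFAULT_MIN_NUCLEI
) -> NucleiField:
    """The eligible field with maximal LI; ties broken by field_id order."""
    eligible = [f for f in fields if f.total >= min_nuclei]
    if not eligible:
        raise ValidationError(
            f"no field has at least {min_nuclei} nuclei; cannot pick a hot spot"
        )
    return min(eligible, key=lambda f: (-field_li(f), f.field_id))


def ki67_score_from_fields(
    fields: Iterable[NucleiField],
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
    bins: ScoreBins = DEFAULT_BINS,
) -> int:
    """Hot-spot LI mapped to the 0/1/2 Ki-67 score."""
    return score_ki67(field_li(select_hotspot(fields, min_nuclei)), bins)


def read_fields(path) -> list[NucleiField]:
    """Read a field CSV (columns field_id, positive, negative)."""
    df = pd.read_csv(path, dtype={"field_id": str})
    missing = set(FIELD_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"field table missing columns: {sorted(missing)}")
    return [
        NucleiField(str(r.field_id), int(r.positive), int(r.negative))
        for r in df.itertuples()
    ]


def write_fields(fields: Sequence[NucleiField], path) -> None:
    pd.DataFrame(
        [{"field_id": f.field_id, "positive": f.positive, "negative": f.negative} for f in fields],
        columns=list(FIELD_COLUMNS),
    ).to_csv(path, index=False)
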