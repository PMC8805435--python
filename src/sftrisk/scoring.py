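"""Point-based metastasis-risk scoring for solitary fibrous tumor.

Implements four models that sum small integer component scores into a total
and map the total to a risk category:

``demicco3``
    age + tumor size + mitotic frequency; low 0-2, intermediate 3-4, high 5-6.
``demicco4``
    adds a necrosis point; low 0-3, intermediate 4-5, high 6-7.
``modified3`` / ``modified4``
    the same models with the Ki-67 labeling-index score substituted for the
    mitotic-frequency score.

Component bins (all half-open, closed on the higher-score side):

========  =======================================  =========
variable  bins                                     scores
========  =======================================  =========
age       [0, 55) / [55, inf)                      0 / 1
size      [0, 5) / [5, 10) / [10, 15) / [15, inf)  0 / 1 / 2 / 3
mitoses   {0} / (0, 2) / [2, inf)                  0 / 1 / 2
Ki-67 LI  [0, 1) / [1, 10) / [10, 100]             0 / 1 / 2
necrosis  [0, 10) / [10, 100]                      0 / 1
========  =======================================  =========

The published mitotic bins (0 / 0.5-1.5 / >= 2 per mm^2) leave gaps at
(0, 0.5) and (1.5, 2); any nonzero value below 2 scores 1 here, which keeps
the printed anchors and preserves monotonicity.

Bin edges and category cut-offs live in :class:`ScoreBins` so the four models
are data, not code; ``ScoreBins.from_json`` loads an alternative definition.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import pandas as pd

from .records import PatientRecord, ValidationError

MODELS = ("demicco3", "demicco4", "modified3", "modified4")
CATEGORIES = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ScoreBins:
    """Component bin edges and category cut-offs for the risk models.

    ``three_var_cuts`` / ``four_var_cuts`` give the largest total still in
    the low and intermediate categories respectively.
    """

    age_cut: float = 55.0
    size_cuts: tuple[float, ...] = (5.0, 10.0, 15.0)
    mitoses_high: float = 2.0
    ki67_cuts: tuple[float, float] = (1.0, 10.0)
    necrosis_cut: float = 10.0
    three_var_cuts: tuple[int, int] = (2, 4)
    four_var_cuts: tuple[int, int] = (3, 5)

    @classmethod
    def from_json(cls, path) -> "ScoreBins":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown score-bin keys: {sorted(unknown)}")
        for key in ("size_cuts", "ki67_cuts", "three_var_cuts", "four_var_cuts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path) -> None:
        data = {
            f: getattr(self, f)
            for f in self.__dataclass_fields__
        }
        data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


DEFAULT_BINS = ScoreBins()


@dataclass(frozen=True)
class ComponentScores:
    age_score: int
    size_score: int
    mitotic_score: int
    ki67_score: int
    necrosis_score: int


@dataclass(frozen=True)
class RiskAssignment:
    """Result of applying one risk model to one patient."""

    model: str
    components: ComponentScores
    total_points: int
    category: str
    dichotomized: str  # "low" or "intermediate_high"


def score_age(age: float, bins: ScoreBins = DEFAULT_BINS) -> int:
    """Age point: 0 below 55 years, 1 at or above."""
    if age < 0:
        raise ValidationError(f"age must be non-negative, got {age}")
    return 0 if age < bins.age_cut else 1


def score_size(tumor_size_cm: float, bins: ScoreBins = DEFAULT_BINS) -> int:
    """Tumor-size point: bin index over [0,5), [5,10), [10,15), [15,inf) cm."""
    if not tumor_size_cm > 0:
        raise ValidationError(f"tumor size must be positive, got {tumor_size_cm}")
    score = 0
    for cut in bins.size_cuts:
        if tumor_size_cm >= cut:
            score += 1
    return score


def score_mitoses(mitoses_per_mm2: float, bins: ScoreBins = DEFAULT_BINS) -> int:
    """Mitotic-frequency point: 0 for none, 2 at >= 2/mm^2, else 1."""
    if mitoses_per_mm2 < 0:
        raise ValidationError(
            f"mitotic count must be non-negative, got {mitoses_per_mm2}"
        )
    if mitoses_per_mm2 == 0:
        return 0
    return 2 if mitoses_per_mm2 >= bins.mitoses_high else 1


def score_ki67(ki67_li_pct: float, bins: ScoreBins = DEFAULT_BINS) -> int:
    """Ki-67 labeling-index point: 0 below 1%, 1 in [1,10)%, 2 at >= 10%."""
    if not 0 <= ki67_li_pct <= 100:
        raise ValidationError(f"Ki-67 LI must be in [0, 100], got {ki67_li_pct}")
    low, high = bins.ki67_cuts
    if ki67_li_pct < low:
        return 0
    return 2 if ki67_li_pct >= high else 1


def score_necrosis(necrosis_pct: float, bins: ScoreBins = DEFAULT_BINS) -> int:
    """Necrosis point: 0 below 10% tumor necrosis, 1 at or above."""
    if not 0 <= necrosis_pct <= 100:
        raise ValidationError(f"necrosis must be in [0, 100], got {necrosis_pct}")
    return 0 if necrosis_pct < bins.necrosis_cut else 1


def component_scores(record: PatientRecord, bins: ScoreBins = DEFAULT_BINS) -> ComponentScores:
    return ComponentScores(
        age_score=score_age(record.age, bins),
        size_score=score_size(record.tumor_size_cm, bins),
        mitotic_score=score_mitoses(record.mitoses_per_mm2, bins),
        ki67_score=score_ki67(record.ki67_li_pct, bins),
        necrosis_score=score_necrosis(record.necrosis_pct, bins),
    )


def _model_components(model: str) -> tuple[str, ...]:
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    proliferation = "ki67_score" if model.startswith("modified") else "mitotic_score"
    parts = ("age_score", "size_score", proliferation)
    if model.endswith("4"):
        parts += ("necrosis_score",)
    return parts


def categorize(model: str, total_points: int, bins: ScoreBins = DEFAULT_BINS) -> str:
    """Map a total to low/intermediate/high under the model's cut-offs."""
    cuts = bins.four_var_cuts if model in ("demicco4", "modified4") else bins.three_var_cuts
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    if total_points <= cuts[0]:
        return "low"
    return "intermediate" if total_points <= cuts[1] else "high"


def assign_risk(
    record: PatientRecord, model: str, bins: ScoreBins = DEFAULT_BINS
) -> RiskAssignment:
    """Score one patient under one model.

    Returns total points, risk category and the low vs intermediate/high
    dichotomization used for two-group survival comparison.
    """
    comps = component_scores(record, bins)
    total = sum(getattr(comps, part) for part in _model_components(model))
    category = categorize(model, total, bins)
    return RiskAssignment(
        model=model,
        components=comps,
        total_points=total,
        category=category,
        dichotomized="low" if category == "low" else "intermediate_high",
    )


_COMPONENT_RANGES = {
    "age_score": (0, 1),
    "size_score": (0, 1, 2, 3),
    "mitotic_score": (0, 1, 2),
    "ki67_score": (0, 1, 2),
    "necrosis_score": (0, 1),
}


def enumerate_score_space(model: str, bins: ScoreBins = DEFAULT_BINS) -> pd.DataFrame:
    """Exhaustive table of the model's component-score product space.

    One row per combination (24 for three-variable models, 48 with the
    necrosis point), with the resulting total and category. Serves as the
    oracle that category bins tile every attainable total.
    """
    parts = _model_components(model)
    rows = []
    for combo in itertools.product(*(_COMPONENT_RANGES[p] for p in parts)):
        total = sum(combo)
        rows.append(
            dict(zip(parts, combo))
            | {"total_points": total, "category": categorize(model, total, bins)}
        )
    return pd.DataFrame(rows)
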