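"""Table-1-style cohort report.

One block per clinicopathological variable in the study's table order:
per-level patient counts and percentages, 5-year metastasis-free survival
with its 95% confidence interval, and the log-rank p-value across the
variable's levels. The four risk-model blocks reuse the scoring module; the
modified models are reported in their dichotomized (low vs
intermediate/high) form.

Formatting conventions: percentages rounded half-up to one decimal;
p-values shown to three decimals with very small values floored at
"<0.001"; a stratum with no events before 60 months reports 100% MFS with
the confidence interval replaced by a footnote marker ("a"), matching the
convention "95% CI was not calculated because of no events until 5 years".
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import pandas as pd

from .records import PatientRecord, ValidationError
from .scoring import DEFAULT_BINS, ScoreBins, assign_risk, component_scores
from .survival import (
    FIVE_YEARS_MONTHS,
    km_estimate,
    logrank_test,
    mfs_dataset,
    survival_at,
)

FOOTNOTE_MARKER = "a"
FOOTNOTE_TEXT = "95% CI was not calculated because of no events until 5 years"


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (so 18.65 -> 18.7, not banker's 18.6)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, n: int, decimals: int = 1) -> float:
    if n <= 0:
        raise ValidationError("percentage denominator must be positive")
    return round_half_up(100.0 * count / n, decimals)


def format_p(p: float) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    if p < 0.0005:
        return "<0.001"
    return f"{round_half_up(p, 3):.3f}"


def _blocks(bins: ScoreBins) -> list[tuple[str, list[tuple[str, Callable]]]]:
    """(variable, [(level label, membership predicate)]) in table order."""

    def comp(record):
        return component_scores(record, bins)

    def risk(record, model):
        return assign_risk(record, model, bins)

    return [
        (
            "Age (years)",
            [
                ("< 55 (score 0)", lambda r: comp(r).age_score == 0),
                (">= 55 (score 1)", lambda r: comp(r).age_score == 1),
            ],
        ),
        (
            "Sex",
            [
                ("Male", lambda r: r.sex == "male"),
                ("Female", lambda r: r.sex == "female"),
            ],
        ),
        (
            "Location",
            [
                ("IT", lambda r: r.location == "intrathoracic"),
                ("IA", lambda r: r.location == "intra_abdominal"),
                ("CNS", lambda r: r.location == "cns"),
                ("Other", lambda r: r.location == "other"),
            ],
        ),
        (
            "Tumor size (cm)",
            [
                ("0-4.9 (score 0)", lambda r: comp(r).size_score == 0),
                ("5-9.9 (score 1)", lambda r: comp(r).size_score == 1),
                ("10-14.9 (score 2)", lambda r: comp(r).size_score == 2),
                (">= 15 (score 3)", lambda r: comp(r).size_score == 3),
            ],
        ),
        (
            "Mitoses/mm2",
            [
                ("0 (score 0)", lambda r: comp(r).mitotic_score == 0),
                ("0.5-1.5 (score 1)", lambda r: comp(r).mitotic_score == 1),
                (">= 2 (score 2)", lambda r: comp(r).mitotic_score == 2),
            ],
        ),
        (
            "Ki-67 LI (%)",
            [
                ("< 1 (score 0)", lambda r: comp(r).ki67_score == 0),
                ("1-10 (score 1)", lambda r: comp(r).ki67_score == 1),
                (">= 10 (score 2)", lambda r: comp(r).ki67_score == 2),
            ],
        ),
        (
            "Tumor necrosis (%)",
            [
                ("< 10 (score 0)", lambda r: comp(r).necrosis_score == 0),
                (">= 10 (score 1)", lambda r: comp(r).necrosis_score == 1),
            ],
        ),
        (
            "Dedifferentiation",
            [
                ("Present", lambda r: r.dedifferentiation),
                ("Absent", lambda r: not r.dedifferentiation),
            ],
        ),
        (
            "Three-variable risk model (age, size, mitoses)",
            [
                ("Low (0-2 points)", lambda r: risk(r, "demicco3").category == "low"),
                (
                    "Intermediate (3-4 points)",
                    lambda r: risk(r, "demicco3").category == "intermediate",
                ),
                ("High (5-6 points)", lambda r: risk(r, "demicco3").category == "high"),
            ],
        ),
        (
            "Four-variable risk model (age, size, mitoses, necrosis)",
            [
                ("Low (0-3 points)", lambda r: risk(r, "demicco4").category == "low"),
                (
                    "Intermediate (4-5 points)",
                    lambda r: risk(r, "demicco4").category == "intermediate",
                ),
                ("High (6-7 points)", lambda r: risk(r, "demicco4").category == "high"),
            ],
        ),
        (
            "Modified three-variable model (age, size, Ki-67 LI)",
            [
                (
                    "Low risk (0-2 points)",
                    lambda r: risk(r, "modified3").dichotomized == "low",
                ),
                (
                    "Intermediate/high risk (3-6 points)",
                    lambda r: risk(r, "modified3").dichotomized == "intermediate_high",
                ),
            ],
        ),
        (
            "Modified four-variable model (age, size, Ki-67 LI, necrosis)",
            [
                (
                    "Low risk (0-3 points)",
                    lambda r: risk(r, "modified4").dichotomized == "low",
                ),
                (
                    "Intermediate/high risk (4-7 points)",
                    lambda r: risk(r, "modified4").dichotomized == "intermediate_high",
                ),
            ],
        ),
    ]


def _block_p(strata: Sequence[Sequence[PatientRecord]]) -> float:
    """Log-rank p across the non-empty strata; NaN when not computable."""
    groups = [mfs_dataset(s) for s in strata if len(s) > 0]
    if len(groups) < 2:
        return float("nan")
    try:
        return logrank_test(groups).p_value
    except ValidationError:
        return float("nan")


def table1(
    records: Sequence[PatientRecord], bins: ScoreBins = DEFAULT_BINS
) -> pd.DataFrame:
    """Build the full cohort report as a tidy DataFrame.

    Columns: variable, level, count, percent, mfs_5yr_pct,
    ci_lower_pct/ci_upper_pct (NaN when the footnote applies or the stratum
    is empty), footnote (marker or ""), p_value (repeated within a block,
    NaN when not computable).
    """
    if len(records) == 0:
        raise ValidationError("table1 needs at least one record")
    n = len(records)
    rows = []
    for variable, levels in _blocks(bins):
        strata = [[r for r in records if pred(r)] for _, pred in levels]
        p = _block_p(strata)
        for (label, _), stratum in zip(levels, strata):
            count = len(stratum)
            mfs = ci_lo = ci_hi = float("nan")
            footnote = ""
            if count > 0:
                point = survival_at(km_estimate(mfs_dataset(stratum)), FIVE_YEARS_MONTHS)
                mfs = round_half_up(100.0 * point.estimate, 1)
                if point.ci_defined:
                    ci_lo = round_half_up(100.0 * point.ci_lower, 1)
                    ci_hi = round_half_up(100.0 * point.ci_upper, 1)
                else:
                    footnote = FOOTNOTE_MARKER
            rows.append(
                {
                    "variable": variable,
                    "level": label,
                    "count": count,
                    "percent": percent(count, n),
                    "mfs_5yr_pct": mfs,
                    "ci_lower_pct": ci_lo,
                    "ci_upper_pct": ci_hi,
                    "footnote": footnote,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def table1_markdown(report: pd.DataFrame) -> str:
    """Render the report as a human-readable Markdown table."""
    lines = [
        "| Variable | Patients, n (%) | 5-year MFS (%) (95% CI) | Log-rank p |",
        "| --- | --- | --- | --- |",
    ]
    prev_variable = None
    for _, row in report.iterrows():
        if row["variable"] != prev_variable:
            lines.append(f"| **{row['variable']}** |  |  | {format_p(row['p_value'])} |")
            prev_variable = row["variable"]
        if row["count"] == 0:
            mfs_cell = "-"
        elif row["footnote"]:
            mfs_cell = f"{row['mfs_5yr_pct']:.1f} (^{row['footnote']}^)"
        else:
            mfs_cell = (
                f"{row['mfs_5yr_pct']:.1f} "
                f"({row['ci_lower_pct']:.1f}-{row['ci_upper_pct']:.1f})"
            )
        lines.append(
            f"| {row['level']} | {row['count']} ({row['percent']:.1f}) | {mfs_cell} |  |"
        )
    lines.append("")
    lines.append(f"^{FOOTNOTE_MARKER}^ {FOOTNOTE_TEXT}")
    return "\n".join(lines)
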