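"""Seeded synthetic SFT cohorts with a configurable two-group survival model.

No per-patient data accompany the study this package models, so every
downstream stage (scoring, survival statistics, reporting) is exercised on
synthetic cohorts. The generator draws each covariate's *category*
independently from configurable marginal probabilities — the defaults are
the published cohort's marginal proportions (n = 43; e.g. 24/43 aged >= 55,
6/43 tumors >= 15 cm, 4/43 with Ki-67 >= 10%) — then a raw value uniformly
within the category's bin, truncating the open-ended bins at plausible
clinical bounds (age 95 y, size 25 cm, mitoses 10/mm^2, Ki-67 80%).

Survival depends on the covariates only through the dichotomized risk group
of a chosen model: metastasis times are exponential with per-month hazard
``hazard_low`` or ``hazard_high``, administratively censored at a follow-up
drawn uniformly from ``followup_range`` (default spanning 1-250 months).
Identical configs produce identical cohorts, byte-for-byte in CSV form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ki67 import NucleiField
from .records import PatientRecord, ValidationError
from .scoring import DEFAULT_BINS, MODELS, ScoreBins, categorize

_F = 43.0  # published cohort size, denominator of the default marginals


def _bins_raw_ranges(bins: ScoreBins, cfg: "SyntheticCohortConfig"):
    """Raw-value sampling interval per category index, per variable."""
    s1, s2, s3 = bins.size_cuts
    k1, k2 = bins.ki67_cuts
    return {
        "age": [(cfg.age_min, bins.age_cut), (bins.age_cut, cfg.age_max)],
        "size": [(cfg.size_min, s1), (s1, s2), (s2, s3), (s3, cfg.size_max)],
        # score 0 is exactly zero mitoses; score 1 spans the printed 0.5-1.5 bin
        "mitoses": [(0.0, 0.0), (0.5, 1.5), (bins.mitoses_high, cfg.mitoses_max)],
        "ki67": [(0.0, k1), (k1, k2), (k2, cfg.ki67_max)],
        "necrosis": [(0.0, bins.necrosis_cut), (bins.necrosis_cut, 100.0)],
    }


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterization of the cohort simulator.

    Probabilities are per-category marginals (must sum to 1 within each
    variable); hazards are exponential metastasis rates per month for the
    dichotomized low vs intermediate/high groups under ``dichotomize_model``.
    """

    n: int = 43
    seed: int = 0
    p_age: tuple[float, float] = (19 / _F, 24 / _F)
    p_size: tuple[float, float, float, float] = (24 / _F, 10 / _F, 3 / _F, 6 / _F)
    p_mitoses: tuple[float, float, float] = (34 / _F, 4 / _F, 5 / _F)
    p_ki67: tuple[float, float, float] = (15 / _F, 24 / _F, 4 / _F)
    p_necrosis: tuple[float, float] = (40 / _F, 3 / _F)
    p_male: float = 21 / _F
    p_location: tuple[float, float, float, float] = (10 / _F, 12 / _F, 6 / _F, 15 / _F)
    p_dediff: float = 2 / _F
    hazard_low: float = 0.0005
    hazard_high: float = 0.005
    dichotomize_model: str = "modified3"
    followup_range: tuple[float, float] = (1.0, 250.0)
    # truncation of the open-ended raw-value bins
    age_min: float = 18.0
    age_max: float = 95.0
    size_min: float = 1.0
    size_max: float = 25.0
    mitoses_max: float = 10.0
    ki67_max: float = 80.0
    bins: ScoreBins = field(default_factory=ScoreBins)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"cohort size must be >= 1, got {self.n}")
        if self.dichotomize_model not in MODELS:
            raise ValidationError(
                f"unknown dichotomize_model {self.dichotomize_model!r}"
            )
        for name in ("p_age", "p_size", "p_mitoses", "p_ki67", "p_necrosis", "p_location"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"{name} must be non-negative and sum to 1, got {tuple(p)}"
                )
        for name in ("p_male", "p_dediff"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must be a probability, got {p}")
        if self.hazard_low < 0 or self.hazard_high < 0:
            raise ValidationError("hazards must be non-negative")
        lo, hi = self.followup_range
        if not 0 < lo <= hi:
            raise ValidationError(f"bad followup_range {self.followup_range}")


# rounding quantum of the emitted raw value, per variable
_DECIMALS = {"age": 1, "size": 2, "mitoses": 2, "ki67": 2, "necrosis": 1}


def _uniform_within(rng: np.random.Generator, interval, size: int, decimals: int) -> np.ndarray:
    """Uniform draw within [lo, hi), rounded but clamped inside the bin.

    Clamping keeps a rounded boundary value (e.g. necrosis 9.96 -> 10.0)
    from crossing into the neighbouring score bin.
    """
    lo, hi = interval
    if hi <= lo:
        return np.full(size, lo)
    # bin edges all sit on the rounding grid, so clamping to hi - quantum
    # (one quantum below the upper edge) suffices
    quantum = round(10.0 ** -decimals, decimals)
    vals = np.round(rng.uniform(lo, hi, size), decimals)
    return np.clip(vals, lo, np.round(hi - quantum, decimals))


def generate_cohort(config: SyntheticCohortConfig) -> list[PatientRecord]:
    """Draw a fully reproducible synthetic cohort of ``config.n`` patients."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    bins = config.bins
    ranges = _bins_raw_ranges(bins, config)

    cat = {
        "age": rng.choice(2, size=n, p=config.p_age),
        "size": rng.choice(4, size=n, p=config.p_size),
        "mitoses": rng.choice(3, size=n, p=config.p_mitoses),
        "ki67": rng.choice(3, size=n, p=config.p_ki67),
        "necrosis": rng.choice(2, size=n, p=config.p_necrosis),
    }
    raw = {}
    for var, idx in cat.items():
        vals = np.empty(n)
        for c, interval in enumerate(ranges[var]):
            mask = idx == c
            vals[mask] = _uniform_within(rng, interval, int(mask.sum()), _DECIMALS[var])
        raw[var] = vals

    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    location = rng.choice(
        ["intrathoracic", "intra_abdominal", "cns", "other"],
        size=n,
        p=config.p_location,
    )
    dediff = rng.random(n) < config.p_dediff

    # survival through the dichotomized group of the chosen model
    prolif = (
        cat["ki67"]
        if config.dichotomize_model.startswith("modified")
        else cat["mitoses"]
    )
    totals = cat["age"] + cat["size"] + prolif
    if config.dichotomize_model.endswith("4"):
        totals = totals + cat["necrosis"]
    is_low = np.array(
        [categorize(config.dichotomize_model, int(t), bins) == "low" for t in totals]
    )
    hazards = np.where(is_low, config.hazard_low, config.hazard_high)
    with np.errstate(divide="ignore"):
        scale = np.where(hazards > 0, 1.0 / np.where(hazards > 0, hazards, 1.0), np.inf)
    t_event = np.where(np.isinf(scale), np.inf, rng.standard_exponential(n) * scale)
    follow_up = rng.uniform(*config.followup_range, size=n)
    metastasis = t_event <= follow_up

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:0{width}d}",
                age=round(float(raw["age"][i]), 1),
                sex=str(sex[i]),
                location=str(location[i]),
                tumor_size_cm=round(float(raw["size"][i]), 2),
                mitoses_per_mm2=round(float(raw["mitoses"][i]), 2),
                ki67_li_pct=round(float(raw["ki67"][i]), 2),
                necrosis_pct=round(float(raw["necrosis"][i]), 1),
                dedifferentiation=bool(dediff[i]),
                follow_up_months=round(float(follow_up[i]), 1),
                metastasis=bool(metastasis[i]),
                # floor at 0.1 so a rounded event time stays strictly positive
                time_to_metastasis_months=(
                    max(0.1, round(float(t_event[i]), 1)) if metastasis[i] else None
                ),
            )
        )
    return records


def generate_fields(
    true_li: float,
    n_fields: int = 10,
    nuclei_per_field: int = 1000,
    hotspot_boost: float = 1.0,
    seed: int = 0,
) -> list[NucleiField]:
    """Binomial nucleus counts per candidate field for the Ki-67 quantifier.

    Every field draws positives at rate ``true_li``/100 except the first,
    the designated hot spot, which uses ``min(100, true_li * hotspot_boost)``.
    """
    if not 0 <= true_li <= 100:
        raise ValidationError(f"true_li must be in [0, 100], got {true_li}")
    if hotspot_boost < 0:
        raise ValidationError(f"hotspot_boost must be non-negative, got {hotspot_boost}")
    if n_fields < 1 or nuclei_per_field < 1:
        raise ValidationError("need at least one field and one nucleus per field")
    rng = np.random.default_rng(seed)
    rates = np.full(n_fields, true_li / 100.0)
    rates[0] = min(100.0, true_li * hotspot_boost) / 100.0
    positives = rng.binomial(nuclei_per_field, rates)
    width = len(str(n_fields))
    return [
        NucleiField(
            field_id=f"field_{i:0{width}d}",
            positive=int(positives[i]),
            negative=int(nuclei_per_field - positives[i]),
        )
        for i in range(n_fields)
    ]
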