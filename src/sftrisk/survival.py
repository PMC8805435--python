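"""Metastasis-free-survival statistics implemented from first principles.

Kaplan-Meier product-limit estimation with Greenwood variance and 95%
confidence bands, step-function evaluation (the "5-year MFS" numbers), and
the k-group log-rank test. An external survival library is deliberately not
used here; it serves only as an independent oracle in the test suite.

Conventions
-----------
* times are months from resection/biopsy; ``event`` true means distant
  metastasis was observed, false means censored at that time.
* ties between an event and a censoring at the same time are resolved events
  first (the censored subject is still in the risk set at that time).
* confidence intervals use Greenwood variance on the complementary log-log
  scale by default (``ci_method="loglog"``); a plain linear band is
  available with ``ci_method="linear"``.
* a survival point earlier than the first event has estimate 1 and an
  *undefined* confidence interval — the reporting layer renders this as the
  "no events until 5 years" footnote rather than a degenerate (100, 100)
  band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import PatientRecord, ValidationError

FIVE_YEARS_MONTHS = 60.0


@dataclass(frozen=True)
class SurvivalSample:
    time: float  # months, > 0
    event: bool  # True = metastasis, False = censored

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"survival time must be positive, got {self.time}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate tabulated at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray  # NaN where the band is undefined
    ci_upper: np.ndarray
    n_total: int
    conf_level: float
    ci_method: str


@dataclass(frozen=True)
class SurvivalPoint:
    estimate: float
    ci_lower: float | None
    ci_upper: float | None

    @property
    def ci_defined(self) -> bool:
        return self.ci_lower is not None


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray  # events per group
    expected: np.ndarray


def _as_time_event(samples) -> tuple[np.ndarray, np.ndarray]:
    samples = list(samples)
    if not samples:
        raise ValidationError("need at least one survival sample")
    if isinstance(samples[0], SurvivalSample):
        times = np.array([s.time for s in samples], dtype=float)
        events = np.array([s.event for s in samples], dtype=bool)
    else:
        times = np.array([t for t, _ in samples], dtype=float)
        events = np.array([bool(e) for _, e in samples], dtype=bool)
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    return times, events


def _km_bands(
    surv: np.ndarray, var: np.ndarray, conf_level: float, method: str
) -> tuple[np.ndarray, np.ndarray]:
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    lower = np.full_like(surv, np.nan)
    upper = np.full_like(surv, np.nan)
    if method == "linear":
        half = z * np.sqrt(var)
        lower = np.clip(surv - half, 0.0, 1.0)
        upper = np.clip(surv + half, 0.0, 1.0)
        return lower, upper
    if method != "loglog":
        raise ValidationError(f"unknown ci_method {method!r}")
    # Greenwood on the log(-log S) scale; undefined at S = 0 or 1.
    interior = (surv > 0.0) & (surv < 1.0)
    s = surv[interior]
    se = np.sqrt(var[interior]) / (s * np.abs(np.log(s)))
    lower[interior] = s ** np.exp(z * se)
    upper[interior] = s ** np.exp(-z * se)
    return lower, upper


def km_estimate(
    samples: Iterable[SurvivalSample] | Iterable[tuple[float, bool]],
    conf_level: float = 0.95,
    ci_method: str = "loglog",
) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time ``t_i`` with ``d_i`` events out of ``n_i``
    at risk, ``S(t_i) = prod_{j<=i} (1 - d_j/n_j)``; Greenwood's formula
    gives ``Var S(t) = S(t)^2 sum_j d_j / (n_j (n_j - d_j))`` (the variance
    term is left infinite when the last subject at risk has the event).
    """
    times, events = _as_time_event(samples)
    n_total = times.size
    event_times = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    d = np.array([((times == t) & events).sum() for t in event_times], dtype=int)
    with np.errstate(divide="ignore"):
        frac = d / at_risk
        surv = np.cumprod(1.0 - frac)
        gw_terms = np.where(
            at_risk > d, d / (at_risk * (at_risk - d).astype(float)), np.inf
        )
    with np.errstate(invalid="ignore"):
        greenwood = surv**2 * np.cumsum(gw_terms)
    greenwood = np.where(surv == 0.0, 0.0, greenwood)  # 0 * inf at S = 0
    lower, upper = _km_bands(surv, greenwood, conf_level, ci_method)
    return KMCurve(
        event_times=event_times,
        at_risk=at_risk,
        events=d,
        survival=surv,
        greenwood_var=greenwood,
        ci_lower=lower,
        ci_upper=upper,
        n_total=n_total,
        conf_level=conf_level,
        ci_method=ci_method,
    )


def survival_at(curve: KMCurve, t: float) -> SurvivalPoint:
    """Right-continuous step evaluation of the curve at time ``t``.

    When no event occurred at or before ``t`` the estimate is 1 and the
    confidence interval is undefined.
    """
    if t < 0:
        raise ValidationError(f"evaluation time must be non-negative, got {t}")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return SurvivalPoint(estimate=1.0, ci_lower=None, ci_upper=None)
    lo, hi = curve.ci_lower[idx], curve.ci_upper[idx]
    return SurvivalPoint(
        estimate=float(curve.survival[idx]),
        ci_lower=None if np.isnan(lo) else float(lo),
        ci_upper=None if np.isnan(hi) else float(hi),
    )


def logrank_test(groups: Sequence[Iterable]) -> LogRankResult:
    """Log-rank test across two or more groups.

    At each pooled event time the observed events per group are compared
    with their expectation under a common risk, with the hypergeometric
    (co)variance; the statistic is the quadratic form over the first
    ``k - 1`` groups and the p-value the chi-square upper tail with
    ``k - 1`` degrees of freedom. The two-group case reduces to the
    familiar ``(O - E)^2 / V``.
    """
    parsed = [_as_time_event(g) for g in groups]
    k = len(parsed)
    if k < 2:
        raise ValidationError("log-rank test needs at least two groups")
    times = np.concatenate([t for t, _ in parsed])
    events = np.concatenate([e for _, e in parsed])
    labels = np.concatenate(
        [np.full(t.size, g, dtype=int) for g, (t, _) in enumerate(parsed)]
    )
    if not events.any():
        raise ValidationError("log-rank statistic undefined with zero events")

    event_times = np.unique(times[events])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = int((events & (times == t)).sum())
        n_g = np.array([(at_risk & (labels == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array(
            [((times == t) & events & (labels == g)).sum() for g in range(k)],
            dtype=float,
        )
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            p = n_g / n
            hyper = d * (n - d) / (n - 1.0)
            cov += hyper * (np.diag(p) - np.outer(p, p))

    diff = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        observed=observed,
        expected=expected,
    )


def mfs_dataset(records: Iterable[PatientRecord]) -> list[SurvivalSample]:
    """Map patient records to metastasis-free-survival samples.

    Metastasis becomes an event at ``time_to_metastasis_months``; everyone
    else — including patients who died without documented metastasis — is
    censored at last follow-up, since distant metastasis is the sole
    endpoint here.
    """
    samples = []
    for rec in records:
        if rec.metastasis:
            samples.append(SurvivalSample(rec.time_to_metastasis_months, True))
        else:
            samples.append(SurvivalSample(rec.follow_up_months, False))
    return samples
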