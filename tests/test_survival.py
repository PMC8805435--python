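"""Kaplan-Meier estimator, Greenwood variance, log-rank test, MFS mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sftrisk.records import ValidationError
from sftrisk.survival import (
    SurvivalSample,
    km_estimate,
    logrank_test,
    mfs_dataset,
    survival_at,
)

from conftest import make_record


def brute_force_km(samples):
    """Independent product-limit: direct loop over sorted event times."""
    times = np.array([t for t, _ in samples], float)
    events = np.array([e for _, e in samples], bool)
    s = 1.0
    out = {}
    for t in sorted(set(times[events])):
        n = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1 - d / n
        out[t] = s
    return out


def brute_force_logrank_2group(g1, g2):
    """Independent two-group (O-E)^2/V accumulation of hypergeometric moments."""
    t1 = np.array([t for t, _ in g1]); e1 = np.array([e for _, e in g1], bool)
    t2 = np.array([t for t, _ in g2]); e2 = np.array([e for _, e in g2], bool)
    times = np.concatenate([t1, t2]); events = np.concatenate([e1, e2])
    o_minus_e = 0.0
    v = 0.0
    for t in sorted(set(times[events])):
        n = (times >= t).sum()
        n1 = (t1 >= t).sum()
        d = ((times == t) & events).sum()
        d1 = ((t1 == t) & e1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


def test_single_event():
    curve = km_estimate([(10.0, True)])
    assert curve.survival.tolist() == [0.0]
    assert survival_at(curve, 5).estimate == 1.0
    assert survival_at(curve, 10).estimate == 0.0


def test_all_censored_gives_flat_curve():
    curve = km_estimate([(5.0, False), (9.0, False)])
    assert curve.event_times.size == 0
    point = survival_at(curve, 60)
    assert point.estimate == 1.0 and not point.ci_defined


def test_worked_example_event_censor_event():
    # event 5, censored 8, event 12: S(5) = 2/3; at t=12 the risk set is 1
    curve = km_estimate([(5, True), (8, False), (12, True)])
    assert curve.survival == pytest.approx([2 / 3, 0.0])
    assert curve.at_risk.tolist() == [3, 1]


def test_greenwood_hand_computation():
    # events at 2 (n=5) and 4 (n=3), censoring at 3
    samples = [(2, True), (3, False), (4, True), (6, False), (7, False)]
    curve = km_estimate(samples)
    s2, s4 = 4 / 5, 4 / 5 * 2 / 3
    assert curve.survival == pytest.approx([s2, s4])
    assert curve.greenwood_var == pytest.approx(
        [s2**2 * (1 / 20), s4**2 * (1 / 20 + 1 / 6)]
    )
    assert curve.ci_lower[0] < s2 < curve.ci_upper[0]


def test_tied_event_and_censoring_keeps_censored_in_risk_set():
    curve = km_estimate([(5, True), (5, False), (9, False)])
    assert curve.at_risk.tolist() == [3]
    assert curve.survival == pytest.approx([2 / 3])


def test_survival_at_step_and_bounds():
    curve = km_estimate([(30.0, True), (80.0, False)])
    assert survival_at(curve, 0).estimate == 1.0
    assert not survival_at(curve, 29.9).ci_defined
    point = survival_at(curve, 60)
    assert point.estimate == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        survival_at(curve, -1)


def test_km_linear_ci_clipped():
    curve = km_estimate([(5, True), (8, True), (12, False)], ci_method="linear")
    assert np.all(curve.ci_lower >= 0) and np.all(curve.ci_upper <= 1)
    assert np.all(curve.ci_lower <= curve.survival + 1e-12)


def test_km_input_validation():
    with pytest.raises(ValidationError):
        km_estimate([])
    with pytest.raises(ValidationError):
        km_estimate([(0.0, True)])
    with pytest.raises(ValidationError):
        SurvivalSample(-3.0, True)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 40), st.booleans()), min_size=1, max_size=60))
def test_km_matches_brute_force(samples):
    samples = [(float(t), e) for t, e in samples]
    curve = km_estimate(samples)
    expected = brute_force_km(samples)
    assert curve.survival == pytest.approx(
        [expected[t] for t in curve.event_times], abs=1e-12
    )
    # survival non-increasing, at_risk non-increasing, variance terms accumulate
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all(np.diff(curve.at_risk) <= 0)
    finite = np.isfinite(curve.greenwood_var) & (curve.survival > 0)
    ratio = curve.greenwood_var[finite] / curve.survival[finite] ** 2
    assert np.all(np.diff(ratio) >= -1e-12)


def test_no_censoring_equals_empirical_survivor():
    rng = np.random.default_rng(0)
    times = np.round(rng.exponential(30, 80), 1) + 0.1
    curve = km_estimate([(t, True) for t in times])
    for t in curve.event_times:
        assert survival_at(curve, t).estimate == pytest.approx((times > t).mean())


def test_logrank_identical_groups_statistic_zero():
    g = [(5.0, True), (8.0, False), (12.0, True)]
    result = logrank_test([g, list(g)])
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_logrank_label_invariance():
    g1 = [(3.0, True), (6.0, False), (9.0, True)]
    g2 = [(2.0, True), (7.0, True), (11.0, False)]
    a = logrank_test([g1, g2])
    b = logrank_test([g2, g1])
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_logrank_matches_brute_force_two_group():
    rng = np.random.default_rng(3)
    g1 = [(float(t), bool(e)) for t, e in zip(rng.integers(1, 30, 25), rng.random(25) < 0.7)]
    g2 = [(float(t), bool(e)) for t, e in zip(rng.integers(1, 30, 20), rng.random(20) < 0.5)]
    result = logrank_test([g1, g2])
    assert result.statistic == pytest.approx(brute_force_logrank_2group(g1, g2), abs=1e-12)
    assert result.df == 1
    assert result.observed.sum() == pytest.approx(result.expected.sum())


def test_logrank_three_groups_df():
    rng = np.random.default_rng(4)
    groups = [
        [(float(t), True) for t in rng.integers(1, 40, 15)] for _ in range(3)
    ]
    result = logrank_test(groups)
    assert result.df == 2
    assert 0 <= result.p_value <= 1


def test_logrank_input_validation():
    g = [(5.0, True)]
    with pytest.raises(ValidationError):
        logrank_test([g])
    with pytest.raises(ValidationError):
        logrank_test([[(5.0, False)], [(7.0, False)]])


def test_mfs_dataset_mapping(cohort43):
    censored = make_record(follow_up_months=43.0, metastasis=False)
    event = make_record(
        follow_up_months=30.0, metastasis=True, time_to_metastasis_months=12.0
    )
    samples = mfs_dataset([censored, event])
    assert samples[0] == SurvivalSample(43.0, False)
    assert samples[1] == SurvivalSample(12.0, True)
    assert len(mfs_dataset(cohort43)) == 43


def test_record_with_metastasis_requires_time():
    with pytest.raises(ValidationError):
        make_record(metastasis=True, time_to_metastasis_months=None)
    with pytest.raises(ValidationError):
        make_record(
            follow_up_months=10.0, metastasis=True, time_to_metastasis_months=20.0
        )
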