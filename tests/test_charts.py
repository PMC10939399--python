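"""Chart construction: worked examples, brute-force oracles, and path properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgrcusum import (
    AggregateProcess,
    ChartPath,
    ChartSpec,
    ExponentialBaseline,
    HospitalData,
    RiskModel,
    SubjectRecord,
    aggregate_processes,
    bernoulli_chart,
    bk_chart,
    cgi_chart,
    cgr_chart,
    compute_chart,
    detection_time,
    funnel_plot,
)
from cgrcusum.charts import glr_window_statistic
from conftest import random_aggregate


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_cgi(agg, t, cap=None, theta_grid=None):
    """sup over a theta grid of theta*N - (exp(theta)-1)*Lambda."""
    n = float(agg.n_at([t])[0])
    lam = float(agg.lambda_at([t])[0])
    hi = np.log(cap) if cap else 8.0
    grid = theta_grid if theta_grid is not None else np.linspace(0.0, hi, 20001)
    return float(np.max(grid * n - np.expm1(grid) * lam))


def brute_cgr(agg, t, cap=None):
    """Exhaustive python scan over every suffix nu, incl. the empty one."""
    best = 0.0
    lam_i = agg.per_subject_lambda_at(t)
    n_i = agg.per_subject_n_at(t)
    for nu in range(agg.n_subjects + 1):
        n = n_i[nu:].sum()
        lam = lam_i[nu:].sum()
        if n == 0:
            continue
        th = np.log(n / lam)
        th = min(max(th, 0.0), np.log(cap) if cap else np.inf)
        best = max(best, th * n - np.expm1(th) * lam)
    return best


def brute_bk(agg, t, theta1):
    """Def-4 max over candidate window starts: 0, failure times and their left limits."""
    n_t = float(agg.n_at([t])[0])
    lam_t = float(agg.lambda_at([t])[0])
    cands = [0.0]
    for tf in agg.failure_times[agg.failure_times <= t]:
        cands.extend([tf, np.nextafter(tf, -np.inf)])
    cands.extend(np.linspace(0.0, t, 257))  # dense backup grid
    best = 0.0
    for s in cands:
        n_w = n_t - float(agg.n_at([s])[0])
        lam_w = lam_t - float(agg.lambda_at([s])[0])
        best = max(best, theta1 * n_w - np.expm1(theta1) * lam_w)
    return best


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------


class TestWorkedExamples:
    def test_cgi_single_failure(self, single_failure):
        path = cgi_chart(single_failure, [10.0])
        assert path.values[0] == pytest.approx(np.log(10) - 0.9, abs=1e-9)
        assert path.values[0] == pytest.approx(1.402585, abs=1e-6)
        # oracle: sup over a theta grid
        assert path.values[0] == pytest.approx(brute_cgi(single_failure, 10.0),
                                               abs=1e-6)

    def test_cgi_capped(self, single_failure):
        path = cgi_chart(single_failure, [10.0], cap=6.0)
        assert path.values[0] == pytest.approx(np.log(6) - 0.5, abs=1e-9)

    def test_cgi_zero_before_first_failure(self, single_failure):
        assert cgi_chart(single_failure, [5.0]).values[0] == 0.0

    def test_cgr_equals_cgi_for_single_subject(self, single_failure):
        assert cgr_chart(single_failure, [10.0]).values[0] == pytest.approx(
            1.402585, abs=1e-6)

    def test_cgr_two_subject_suffix_selection(self, exp_model):
        # subject 1 censored with Lambda=0.5, subject 2 fails with Lambda=0.1:
        # the best suffix drops subject 1
        hosp = HospitalData("h", [SubjectRecord("s1", 0.0, 50.0, False),
                                  SubjectRecord("s2", 0.0, 10.0, True)], horizon=50)
        agg = aggregate_processes(hosp, exp_model)
        t = 50.0
        val = cgr_chart(agg, [t]).values[0]
        assert val == pytest.approx(1.402585, abs=1e-6)
        assert brute_cgr(agg, t) == pytest.approx(val, abs=1e-12)
        # and the nu=1 candidate is the CGI value
        assert cgi_chart(agg, [t]).values[0] == pytest.approx(0.110826, abs=1e-6)

    def test_bk_jump_and_drift(self, exp_model):
        hosp = HospitalData("h", [SubjectRecord("a", 0.0, 10.0, True),
                                  SubjectRecord("b", 0.0, 30.0, False)], horizon=30)
        agg = aggregate_processes(hosp, exp_model)
        path = bk_chart(agg, np.log(2), [10.0, 20.0])
        assert path.values[0] == pytest.approx(np.log(2), abs=1e-12)
        # Lambda(10, 20) = 0.1 (only subject b at risk), drift (e^t1 - 1) * 0.1
        assert path.values[1] == pytest.approx(np.log(2) - 0.1, abs=1e-12)

    def test_bk_zero_without_failures(self, exp_model):
        hosp = HospitalData("h", [SubjectRecord("a", 0.0, 50.0, False)], horizon=50)
        agg = aggregate_processes(hosp, exp_model)
        assert np.all(bk_chart(agg, np.log(2), [10.0, 40.0]).values == 0.0)

    def test_detection_time(self):
        path = ChartPath(np.array([1.0, 5.0, 10.0]), np.array([0.0, 0.5, 1.4]))
        assert detection_time(path, 1.0) == 10.0
        assert detection_time(path, 1e9) is None

    def test_detection_at_example_limit(self, single_failure):
        path = cgi_chart(single_failure, [10.0])
        assert detection_time(path, 1.4) == 10.0


# ---------------------------------------------------------------------------
# Brute-force equivalence and path properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(8))
def test_bk_recursion_equals_definition(seed, exp_model):
    rng = np.random.default_rng(seed)
    agg = random_aggregate(rng, exp_model, n_max=10)
    theta1 = rng.uniform(0.2, 1.2)
    ts = np.sort(rng.uniform(1.0, 200.0, 6))
    vals = bk_chart(agg, theta1, ts).values
    for t, v in zip(ts, vals):
        assert v == pytest.approx(brute_bk(agg, t, theta1), abs=1e-9)


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("cap", [None, 6.0])
def test_cgr_scan_equals_bruteforce(seed, cap, exp_model):
    rng = np.random.default_rng(100 + seed)
    agg = random_aggregate(rng, exp_model, n_max=10)
    ts = np.sort(rng.uniform(1.0, 200.0, 6))
    vals = cgr_chart(agg, ts, cap=cap).values
    for t, v in zip(ts, vals):
        assert v == pytest.approx(brute_cgr(agg, t, cap=cap), abs=1e-12)


@given(seed=st.integers(0, 10_000))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_cgr_dominates_cgi_pathwise(seed, ):
    model = RiskModel(ExponentialBaseline(0.01))
    rng = np.random.default_rng(seed)
    agg = random_aggregate(rng, model, n_max=10)
    ts = np.sort(rng.uniform(1.0, 200.0, 8))
    cgr = cgr_chart(agg, ts).values
    cgi = cgi_chart(agg, ts).values
    assert np.all(cgr >= cgi - 1e-12)
    assert np.all(cgi >= 0.0)
    # consequently the CGR signals no later than the CGI at any limit
    for h in (0.3, 1.0, 2.5):
        t_cgr = detection_time(ChartPath(ts, cgr), h)
        t_cgi = detection_time(ChartPath(ts, cgi), h)
        if t_cgi is not None:
            assert t_cgr is not None and t_cgr <= t_cgi


@pytest.mark.parametrize("kind", ["CGI", "CGR", "BK"])
def test_charts_nonincreasing_between_failures(kind, exp_model):
    rng = np.random.default_rng(77)
    agg = random_aggregate(rng, exp_model, n_max=8)
    ft = agg.failure_times
    if ft.size == 0:
        pytest.skip("stream without failures")
    bounds = np.concatenate([[0.0], ft, [ft[-1] + 80.0]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        inner = np.linspace(lo + 1e-6, hi - 1e-6, 24)
        inner = inner[inner > lo + 1e-9]
        if inner.size < 2:
            continue
        if kind == "CGI":
            vals = cgi_chart(agg, inner).values
        elif kind == "CGR":
            vals = cgr_chart(agg, inner).values
        else:
            vals = bk_chart(agg, 0.5, inner).values
        assert np.all(np.diff(vals) <= 1e-9)


def test_detection_monotone_in_h(exp_model):
    rng = np.random.default_rng(5)
    agg = random_aggregate(rng, exp_model, n_max=12)
    ts = np.unique(agg.failure_times)
    if ts.size == 0:
        pytest.skip("no failures")
    path = cgr_chart(agg, ts)
    top = path.values.max()
    assert top > 0  # some failure produces an excursion
    hs = np.linspace(top / 20, 1.5 * top, 15)
    taus = [detection_time(path, h) for h in hs]
    taus = [1e18 if t is None else t for t in taus]  # sentinel for "never"
    assert np.all(np.diff(taus) >= 0)


def test_glr_calendar_reference_bounds_bk(exp_model):
    # G(t) maximizes over theta as well, so it dominates the fixed-theta window max
    rng = np.random.default_rng(17)
    agg = random_aggregate(rng, exp_model, n_max=8)
    if agg.failure_times.size == 0:
        pytest.skip("no failures")
    t = float(agg.failure_times[-1])
    g = glr_window_statistic(agg, t)
    bk = glr_window_statistic(agg, t, theta1=0.4)
    assert g >= bk - 1e-12


# ---------------------------------------------------------------------------
# Bernoulli CUSUM and funnel plot
# ---------------------------------------------------------------------------


def _binary_hospital(n, n_fail, window_rate, horizon=800.0):
    """n subjects entering at 0; n_fail fail at day 10, the rest survive the window."""
    model = RiskModel(ExponentialBaseline(window_rate))
    subjects = [SubjectRecord(f"f{i}", 0.0, 10.0, True) for i in range(n_fail)]
    subjects += [SubjectRecord(f"c{i}", 0.0, 400.0, False) for i in range(n - n_fail)]
    return HospitalData("h", subjects, horizon=horizon), model


class TestBernoulliChart:
    def test_odds_ratio_update_formula(self):
        # p0 = 0.5, OR = 2 -> p1 = 2/3; a failure contributes log(4/3)
        rate = -np.log(0.5) / 365.0
        hosp, model = _binary_hospital(1, 1, rate)
        path = bernoulli_chart(hosp, model, theta1=np.log(2))
        assert path.values[-1] == pytest.approx(np.log(4 / 3), abs=1e-12)
        # oracle: direct Bernoulli likelihood ratio at x = 1
        p0, p1 = 0.5, 2 * 0.5 / (0.5 + 2 * 0.5)
        assert path.values[-1] == pytest.approx(np.log(p1 / p0))

    def test_all_survivors_reflect_at_zero(self):
        rate = -np.log(0.5) / 365.0
        hosp, model = _binary_hospital(5, 0, rate)
        path = bernoulli_chart(hosp, model, theta1=np.log(2))
        assert np.all(path.values == 0.0)

    def test_identical_hypotheses_give_flat_chart(self):
        rate = -np.log(0.5) / 365.0
        hosp, model = _binary_hospital(4, 2, rate)
        path = bernoulli_chart(hosp, model, theta1=0.0)
        assert np.all(path.values == 0.0)

    def test_unscoreable_subject_rejected(self):
        rate = -np.log(0.5) / 365.0
        model = RiskModel(ExponentialBaseline(rate))
        hosp = HospitalData("h", [SubjectRecord("a", 0.0, 100.0, False)], horizon=800)
        with pytest.raises(ValueError):
            bernoulli_chart(hosp, model, theta1=np.log(2))


class TestFunnelPlot:
    def test_on_target_hospital_not_flagged(self):
        rate = -np.log(0.9) / 365.0  # p0 = 0.1
        hosp, model = _binary_hospital(100, 10, rate)
        out = funnel_plot([hosp], model)
        assert not out["flagged"].iloc[0]

    def test_excess_failures_flagged(self):
        rate = -np.log(0.9) / 365.0
        hosp, model = _binary_hospital(100, 20, rate)
        out = funnel_plot([hosp], model, confidence=0.95)
        row = out.iloc[0]
        expected_limit = 0.1 + 1.6449 * np.sqrt(0.1 * 0.9 / 100)
        assert row["limit_prop"] == pytest.approx(expected_limit, abs=1e-3)
        assert row["flagged"]
        # oracle: exact binomial tail also flags 20/100 at p0 = 0.1
        assert funnel_plot([hosp], model, exact=True)["flagged"].iloc[0]

    def test_median_limit_flags_any_excess(self):
        rate = -np.log(0.9) / 365.0
        hosp, model = _binary_hospital(100, 11, rate)
        out = funnel_plot([hosp], model, confidence=0.5)
        assert out["limit_prop"].iloc[0] == pytest.approx(out["expected_prop"].iloc[0])
        assert out["flagged"].iloc[0]

    def test_empty_hospital_omitted_with_warning(self):
        rate = -np.log(0.9) / 365.0
        model = RiskModel(ExponentialBaseline(rate))
        empty = HospitalData("empty", [SubjectRecord("a", 0.0, 5.0, False)], horizon=10)
        hosp, _ = _binary_hospital(10, 1, rate)
        with pytest.warns(UserWarning):
            out = funnel_plot([empty, hosp], model)
        assert list(out["hospital_id"]) == ["h"]


class TestChartSpecValidation:
    def test_theta1_requirements(self):
        with pytest.raises(ValueError):
            ChartSpec("BK")
        with pytest.raises(ValueError):
            ChartSpec("CGI", theta1=0.5)
        with pytest.raises(ValueError):
            ChartSpec("BK", theta1=0.5, mle_cap=6.0)
        ChartSpec("CGR", mle_cap=6.0, control_limit=7.73)

    def test_compute_chart_dispatch_signals(self, exp_model):
        hosp = HospitalData("h", [SubjectRecord("a", 0.0, 10.0, True)], horizon=10)
        path = compute_chart(ChartSpec("CGI", control_limit=1.4), hosp, exp_model)
        assert path.signal_time == 10.0
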