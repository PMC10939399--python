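"""CUSUM chart construction for survival outcomes, plus the funnel-plot baseline.

Four sequential procedures are provided:

* ``cgr_chart`` — generalized CUSUM maximizing the log likelihood ratio jointly
  over the unknown hazard ratio (via its MLE) and the unknown first affected
  subject ``nu`` in entry order.
* ``cgi_chart`` — the same statistic without the maximization over ``nu``;
  a pathwise lower bound for the CGR chart (hence an upper bound for its
  average run length when the hazard is raised from the start).
* ``bk_chart`` — CUSUM with a pre-specified log hazard ratio ``theta1``,
  maximized over an unknown calendar changepoint; admits an O(1) reflected
  recursion.
* ``bernoulli_chart`` — risk-adjusted binary CUSUM on fixed-window outcomes,
  evaluated on a periodic grid.

All continuous-time charts can only increase at failure times, so detection
needs the chart values at failure times only; values between failures are
available for plotting by evaluating at arbitrary times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    AggregateProcess,
    HospitalData,
    RiskModel,
    UnboundedMLEError,
    aggregate_processes,
)

__all__ = [
    "ChartSpec",
    "ChartPath",
    "cgi_chart",
    "cgr_chart",
    "bk_chart",
    "bernoulli_chart",
    "funnel_plot",
    "detection_time",
    "glr_window_statistic",
]

CHART_KINDS = ("CGR", "CGI", "BK", "BERNOULLI")


@dataclass(frozen=True)
class ChartSpec:
    """Which chart to run and with which parameters.

    ``theta1`` is the pre-specified log hazard ratio (BK) or log odds ratio
    (Bernoulli); ``mle_cap`` bounds the estimated hazard ratio ``exp(theta
    hat)`` from above in the generalized charts; ``control_limit`` is the
    signalling threshold h.
    """

    kind: str
    theta1: float | None = None
    mle_cap: float | None = None
    control_limit: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in CHART_KINDS:
            raise ValueError(f"kind must be one of {CHART_KINDS}, got {self.kind!r}")
        needs_theta1 = self.kind in ("BK", "BERNOULLI")
        if needs_theta1 and (self.theta1 is None or not self.theta1 > 0):
            raise ValueError(f"{self.kind} chart requires theta1 > 0")
        if not needs_theta1 and self.theta1 is not None:
            raise ValueError(f"theta1 is only meaningful for BK/Bernoulli charts")
        if self.mle_cap is not None:
            if self.kind not in ("CGR", "CGI"):
                raise ValueError("mle_cap applies to CGR/CGI charts only")
            if not self.mle_cap > 1:
                raise ValueError("mle_cap must be a hazard ratio > 1")
        if self.control_limit is not None and not self.control_limit > 0:
            raise ValueError("control_limit must be > 0")


@dataclass
class ChartPath:
    """Chart values on an ascending time grid, with the first signal time."""

    times: np.ndarray
    values: np.ndarray
    signal_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("evaluation times must be strictly ascending")


def _as_eval_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("evaluation times must be strictly ascending")
    return t


def _log_cap(cap: float | None) -> float:
    if cap is None:
        return np.inf
    if not cap > 1:
        raise ValueError("mle cap must be a hazard ratio > 1")
    return float(np.log(cap))


def cgi_values(n: np.ndarray, lam: np.ndarray, cap: float | None = None) -> np.ndarray:
    """Generalized likelihood-ratio statistic given N(t) and Lambda(t) arrays.

    ``theta_hat N - (exp(theta_hat) - 1) Lambda`` with
    ``theta_hat = clip(log(N / Lambda), 0, log cap)``; zero whenever
    ``N <= Lambda``.
    """
    n = np.asarray(n, dtype=float)
    lam = np.asarray(lam, dtype=float)
    bad = (lam == 0) & (n > 0)
    if np.any(bad) and cap is None:
        raise UnboundedMLEError(
            "failures with zero cumulative intensity require an MLE cap"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        th = np.log(np.where(lam > 0, n / np.where(lam > 0, lam, 1.0), 1.0))
    th = np.where(bad, np.inf, th)
    th = np.clip(th, 0.0, _log_cap(cap))
    vals = th * n - np.expm1(th) * lam
    return np.where(n > 0, vals, 0.0)


def cgi_chart(agg: AggregateProcess, eval_times, cap: float | None = None) -> ChartPath:
    """CGI-CUSUM: the likelihood-ratio statistic for a change from subject one."""
    t = _as_eval_times(eval_times)
    vals = cgi_values(agg.n_at(t), agg.lambda_at(t), cap)
    return ChartPath(t, vals)


def cgr_chart(agg: AggregateProcess, eval_times, cap: float | None = None) -> ChartPath:
    """CGR-CUSUM: maximize the CGI statistic over the first affected subject.

    At each time the statistic is scanned over every suffix ``nu = 1..n+1``
    of the subjects in entry order (the empty suffix contributes zero).  No
    recursion over time exists, so the scan is performed per evaluation time.
    """
    t = _as_eval_times(eval_times)
    log_cap = _log_cap(cap)
    vals = np.zeros(t.size)
    for j, tj in enumerate(t):
        suf_n = agg.suffix_n_at(tj)
        suf_l = agg.suffix_lambda_at(tj)
        bad = (suf_l == 0) & (suf_n > 0)
        if np.any(bad) and cap is None:
            raise UnboundedMLEError(
                "failures with zero cumulative intensity require an MLE cap"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            th = np.log(np.where(suf_l > 0, suf_n / np.where(suf_l > 0, suf_l, 1.0), 1.0))
        th = np.where(bad, np.inf, th)
        th = np.clip(th, 0.0, log_cap)
        cand = np.where(suf_n > 0, th * suf_n - np.expm1(th) * suf_l, 0.0)
        vals[j] = max(0.0, float(np.max(cand)))
    return ChartPath(t, vals)


def bk_running_minima(agg: AggregateProcess, theta1: float):
    """U at failure times and the running infimum of U over continuous time.

    ``U(t) = theta1 N(t) - (exp(theta1) - 1) Lambda(t)`` jumps by ``theta1``
    at each failure and decreases continuously in between, so its infimum
    over ``[0, t]`` is attained at 0 or at a left limit ``U(t_j) - theta1``.
    """
    ft = agg.failure_times
    u_f = theta1 * np.arange(1, ft.size + 1) - np.expm1(theta1) * agg.lambda_at(ft)
    run_min = np.minimum.accumulate(u_f - theta1, ) if ft.size else np.empty(0)
    run_min = np.minimum(run_min, 0.0) if ft.size else run_min
    return u_f, run_min


def bk_chart(agg: AggregateProcess, theta1: float, eval_times) -> ChartPath:
    """BK-CUSUM via the reflected (Lindley) recursion.

    Equals ``max over 0 <= s <= t`` of
    ``theta1 N(s,t) - (exp(theta1)-1) Lambda(s,t)``: jumps by exactly
    ``theta1`` at each failure, drifts down by ``(exp(theta1)-1) dLambda``
    in between, floored at zero.
    """
    if not theta1 > 0:
        raise ValueError("theta1 must be > 0")
    t = _as_eval_times(eval_times)
    ft = agg.failure_times
    u_f, run_min = bk_running_minima(agg, theta1)
    u_t = theta1 * agg.n_at(t) - np.expm1(theta1) * agg.lambda_at(t)
    k = np.searchsorted(ft, t, side="right")  # failures up to and incl. t
    m_t = np.where(k > 0, run_min[np.maximum(k - 1, 0)] if ft.size else 0.0, 0.0)
    vals = np.maximum(0.0, u_t - m_t)
    return ChartPath(t, vals)


def detection_time(path: ChartPath, h: float) -> float | None:
    """First evaluation time at which the chart value reaches the limit h."""
    if not h > 0:
        raise ValueError("control limit h must be > 0")
    hits = np.nonzero(path.values >= h)[0]
    if hits.size == 0:
        return None
    return float(path.times[hits[0]])


def glr_window_statistic(agg: AggregateProcess, t: float, s_grid=None,
                         theta1: float | None = None,
                         cap: float | None = None) -> float:
    """Brute-force calendar-window statistic ``max over s <= t`` (reference).

    With ``theta1 = None`` this is the preliminary generalized chart G(t)
    that estimates theta per window; with a fixed ``theta1`` it is the
    BK statistic by its defining maximization.  Intended as a test oracle
    and diagnostic, not as a production chart.
    """
    if s_grid is None:
        s_grid = np.concatenate([[0.0], agg.failure_times[agg.failure_times <= t]])
    s_grid = np.asarray(s_grid, dtype=float)
    n_t = float(agg.n_at(t)[0])
    lam_t = float(agg.lambda_at(t)[0])
    best = 0.0
    for s in s_grid:
        # N(s,t) counts failures in (s, t]: subtract failures up to and incl. s
        n_w = n_t - float(agg.n_at(s)[0])
        lam_w = lam_t - float(agg.lambda_at(s)[0])
        if theta1 is None:
            val = float(cgi_values(np.array([n_w]), np.array([lam_w]), cap)[0])
        else:
            val = theta1 * n_w - np.expm1(theta1) * lam_w
        best = max(best, val)
    return best


# ---------------------------------------------------------------------------
# Binary-outcome baselines: Bernoulli CUSUM and funnel plot
# ---------------------------------------------------------------------------


def _window_outcome(hospital: HospitalData, model: RiskModel, window: float):
    """Score times, binary outcomes and null probabilities for a fixed window.

    A subject is scoreable ``window`` days after entry; the outcome is
    failure within the window; the null probability is the model-implied
    window failure probability ``1 - exp(-exp(Z'beta) H0(window))``.
    """
    h0w = float(model.baseline.cumulative_hazard(window))
    rows = []
    for s in hospital.subjects:
        score_time = s.entry_time + window
        if score_time > hospital.horizon:
            continue  # not yet scoreable with complete information
        failed = bool(s.event and s.followup_time <= window)
        if not failed and s.followup_time < window:
            raise ValueError(
                f"subject {s.id} censored at {s.followup_time} days cannot be "
                f"scored on a {window}-day window"
            )
        w = model.linear_predictor_weight(s.covariates)
        p0 = -np.expm1(-w * h0w)
        if p0 <= 0.0 or p0 >= 1.0:
            raise ValueError(
                f"subject {s.id} has degenerate window failure probability {p0}"
            )
        rows.append((score_time, failed, p0))
    rows.sort(key=lambda r: r[0])
    if rows:
        st, x, p0 = (np.array(c) for c in zip(*rows))
        return st, x.astype(bool), p0.astype(float)
    return np.empty(0), np.empty(0, dtype=bool), np.empty(0)


def bernoulli_chart(hospital: HospitalData, model: RiskModel, theta1: float,
                    window: float = 365.0, step: float = 30.0) -> ChartPath:
    """Risk-adjusted Bernoulli CUSUM on window outcomes, evaluated periodically.

    Each newly scoreable subject contributes the Bernoulli log likelihood
    ratio ``x log(p1/p0) + (1-x) log((1-p1)/(1-p0))`` with ``p1`` the odds-
    ratio (``exp(theta1)``) shifted null probability; contributions are
    applied one subject at a time with reflection at zero.
    """
    if theta1 < 0:
        raise ValueError("theta1 (log odds ratio) must be >= 0")
    odds_ratio = np.exp(theta1)  # theta1 = 0 gives identical hypotheses, W = 0
    score_t, x, p0 = _window_outcome(hospital, model, window)
    p1 = odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)
    w_obs = np.where(x, np.log(p1 / p0), np.log((1.0 - p1) / (1.0 - p0)))
    grid = np.arange(step, hospital.horizon + step * 1e-9, step)
    vals = np.zeros(grid.size)
    v = 0.0
    j = 0
    for g, gt in enumerate(grid):
        while j < score_t.size and score_t[j] <= gt:
            v = max(0.0, v + float(w_obs[j]))
            j += 1
        vals[g] = v
    return ChartPath(grid, vals)


def funnel_plot(hospitals: Iterable[HospitalData], model: RiskModel,
                window: float = 365.0, confidence: float = 0.95,
                exact: bool = False) -> pd.DataFrame:
    """Cross-sectional funnel comparison of observed vs expected failure proportions.

    Flags a center when its observed window-failure count exceeds the upper
    one-sided ``confidence`` limit of the null distribution of the count
    (normal approximation to the sum of independent Bernoulli(p0_i) by
    default, plain binomial at the mean probability when ``exact=True``).
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    rows = []
    for hosp in hospitals:
        _, x, p0 = _window_outcome(hosp, model, window)
        n = p0.size
        if n == 0:
            warnings.warn(f"hospital {hosp.hospital_id}: no scoreable subjects, omitted")
            continue
        observed = int(np.sum(x))
        mu = float(np.sum(p0))
        if exact:
            limit_count = float(stats.binom.ppf(confidence, n, mu / n))
        else:
            sd = float(np.sqrt(np.sum(p0 * (1.0 - p0))))
            limit_count = mu + stats.norm.ppf(confidence) * sd
        rows.append({
            "hospital_id": hosp.hospital_id,
            "n": n,
            "observed": observed,
            "observed_prop": observed / n,
            "expected_prop": mu / n,
            "limit_prop": limit_count / n,
            "flagged": observed > limit_count,
        })
    return pd.DataFrame(rows, columns=["hospital_id", "n", "observed",
                                       "observed_prop", "expected_prop",
                                       "limit_prop", "flagged"])


def compute_chart(spec: ChartSpec, hospital: HospitalData, model: RiskModel,
                  eval_times=None) -> ChartPath:
    """Dispatch a ChartSpec to the right chart; default grid is the failure times.

    Detection only requires the failure times because the continuous-time
    charts drift downward between failures.
    """
    if spec.kind == "BERNOULLI":
        path = bernoulli_chart(hospital, model, spec.theta1)
    else:
        agg = aggregate_processes(hospital, model)
        if eval_times is None:
            # one chart value per distinct failure time (tied events are
            # processed together)
            eval_times = np.unique(agg.failure_times)
        eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
        if eval_times.size == 0:
            return ChartPath(np.empty(0), np.empty(0), None)
        if spec.kind == "CGI":
            path = cgi_chart(agg, eval_times, spec.mle_cap)
        elif spec.kind == "CGR":
            path = cgr_chart(agg, eval_times, spec.mle_cap)
        else:
            path = bk_chart(agg, spec.theta1, eval_times)
    if spec.control_limit is not None:
        path.signal_time = detection_time(path, spec.control_limit)
    return path
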