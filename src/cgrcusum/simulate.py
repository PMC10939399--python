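"""Synthetic hospital generator, control-limit calibration, and ARL/power studies.

The generator emulates the monitoring setting the charts are designed for:
subjects enter a center by a Poisson process with rate ``psi`` (per day),
draw optional covariates, and fail with cumulative hazard
``m(t) exp(Z'beta) H0(x)`` where the multiplier ``m`` encodes the
deterioration scenario (in control, raised from the start, raised from a
given patient, or raised from a calendar changepoint).  Failure times are
drawn by inversion of the (piecewise) cumulative hazard.

Randomness discipline: one root seed; hospital ``rep`` and time chunk ``k``
index deterministic child streams, so extending the horizon or adding
replicates never reshuffles earlier data, and a run simulated until signal
in chunks equals the same run simulated in one pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _fast
from .charts import ChartPath, ChartSpec, bernoulli_chart, bk_chart, cgi_chart, cgr_chart, detection_time
from .model import (
    AggregateProcess,
    ExponentialBaseline,
    HospitalData,
    RiskModel,
    SubjectRecord,
)

__all__ = [
    "CHUNK_DAYS",
    "ChangepointSpec",
    "CovariateGenerator",
    "StudyDesign",
    "simulate_hospital",
    "simulate_raw_stream",
    "chart_run_length",
    "calibrate_control_limit_type1",
    "calibrate_control_limit_arl",
    "CalibrationResult",
    "run_length_study",
    "power_study",
]

# simulation advances in fixed 4-year blocks; results are invariant to the
# block size only through the per-(rep, chunk) child-stream discipline, so
# the constant is part of the reproducibility contract
CHUNK_DAYS = 1461.0

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ChangepointSpec:
    """How and when the hazard is raised by ``exp(theta)``.

    Modes: ``none`` (in control), ``from_start`` (every subject),
    ``patient_index`` (subjects ``nu, nu+1, ...`` in entry order),
    ``calendar_time`` (hazard multiplier switches at calendar time ``s`` for
    everyone at risk).
    """

    mode: str = "none"
    theta: float = 0.0
    s: float | None = None
    nu: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "from_start", "calendar_time", "patient_index"):
            raise ValueError(f"unknown changepoint mode {self.mode!r}")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.mode == "calendar_time" and (self.s is None or self.s < 0):
            raise ValueError("calendar_time mode requires s >= 0")
        if self.mode == "patient_index" and (self.nu is None or self.nu < 1):
            raise ValueError("patient_index mode requires integer nu >= 1")


@dataclass(frozen=True)
class CovariateGenerator:
    """Independent covariate components: ``("bernoulli", p)`` or ``("normal", mu, sd)``."""

    components: tuple

    def __post_init__(self) -> None:
        for c in self.components:
            if c[0] not in ("bernoulli", "normal"):
                raise ValueError(f"unknown covariate component {c!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cols = []
        for c in self.components:
            if c[0] == "bernoulli":
                cols.append(rng.random(n) < c[1])
            else:
                cols.append(rng.normal(c[1], c[2], n))
        return np.column_stack(cols).astype(float) if cols else np.empty((n, 0))


@dataclass(frozen=True)
class StudyDesign:
    """One simulation scenario: arrivals, null model, deterioration, horizon, seed."""

    psi: float
    model: RiskModel
    changepoint: ChangepointSpec = ChangepointSpec()
    covariate_gen: CovariateGenerator | None = None
    horizon: float = 6 * DAYS_PER_YEAR
    n_hospitals: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.psi > 0:
            raise ValueError("psi must be > 0")
        if not self.horizon > 0:
            raise ValueError("horizon must be > 0")
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if self.model.coefficients and self.covariate_gen is None:
            raise ValueError("model has coefficients but no covariate generator")


# ---------------------------------------------------------------------------
# Stream generation
# ---------------------------------------------------------------------------


def _chunk_rng(seed: int, rep: int, chunk: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(rep), int(chunk)))
    return np.random.default_rng(ss)


def _invert_failure(e_std, entry, weight, design: StudyDesign, global_index):
    """Failure durations by inversion of the scenario cumulative hazard.

    ``e_std`` are standard-exponential draws; the subject fails at duration x
    solving ``m * w * H0(x) = E`` (constant multiplier m) or the piecewise
    version with the multiplier switching at the calendar changepoint.
    """
    cp = design.changepoint
    base = design.model.baseline
    e_theta = math.exp(cp.theta)
    if cp.mode == "none" or cp.theta == 0.0:
        return np.asarray(base.inverse_cumulative_hazard(e_std / weight), dtype=float)
    if cp.mode == "from_start":
        return np.asarray(base.inverse_cumulative_hazard(e_std / (weight * e_theta)), dtype=float)
    if cp.mode == "patient_index":
        m = np.where(global_index >= cp.nu, e_theta, 1.0)
        return np.asarray(base.inverse_cumulative_hazard(e_std / (weight * m)), dtype=float)
    # calendar_time: multiplier 1 until calendar s, exp(theta) afterwards;
    # the subject-time kink sits at x_s = max(0, s - entry)
    x_s = np.maximum(0.0, cp.s - entry)
    h0_xs = np.asarray(base.cumulative_hazard(x_s), dtype=float)
    thr = weight * h0_xs
    pre = e_std <= thr
    x = np.empty_like(e_std)
    x[pre] = np.asarray(base.inverse_cumulative_hazard(e_std[pre] / weight[pre]), dtype=float)
    target = h0_xs[~pre] + (e_std[~pre] - thr[~pre]) / (weight[~pre] * e_theta)
    x[~pre] = np.asarray(base.inverse_cumulative_hazard(target), dtype=float)
    return x


class _Stream:
    """Lazily extended raw stream of one simulated hospital (uncensored)."""

    def __init__(self, design: StudyDesign, rep: int):
        self.design = design
        self.rep = rep
        self.entry = np.empty(0)
        self.duration = np.empty(0)
        self.weight = np.empty(0)
        self.covariates: list[np.ndarray] = []
        self.n_chunks = 0

    @property
    def generated_until(self) -> float:
        return self.n_chunks * CHUNK_DAYS

    def extend_to(self, t: float) -> None:
        while self.generated_until < t:
            k = self.n_chunks
            rng = _chunk_rng(self.design.seed, self.rep, k)
            a, b = k * CHUNK_DAYS, (k + 1) * CHUNK_DAYS
            count = rng.poisson(self.design.psi * (b - a))
            s = np.sort(rng.uniform(a, b, count))
            if self.design.covariate_gen is not None:
                z = self.design.covariate_gen.sample(rng, count)
                w = self.design.model.weights(z)
            else:
                z = np.empty((count, 0))
                w = np.ones(count)
            e_std = rng.exponential(size=count)
            gidx = self.entry.size + 1 + np.arange(count)  # 1-based entry order
            x = _invert_failure(e_std, s, w, self.design, gidx)
            self.entry = np.concatenate([self.entry, s])
            self.duration = np.concatenate([self.duration, x])
            self.weight = np.concatenate([self.weight, w])
            self.covariates.append(z)
            self.n_chunks += 1

    @property
    def exit(self) -> np.ndarray:
        return self.entry + self.duration

    def covariate_matrix(self) -> np.ndarray:
        if not self.covariates:
            return np.empty((0, 0))
        return np.vstack(self.covariates)


def simulate_raw_stream(design: StudyDesign, rep: int = 0, until: float | None = None):
    """Entry times, failure durations and weights, uncensored, up to ``until``.

    Subjects entering before ``until`` are returned with their full failure
    duration (which may extend past ``until``); administrative censoring is
    applied by :func:`simulate_hospital`, not here.
    """
    until = design.horizon if until is None else until
    st = _Stream(design, rep)
    st.extend_to(until)
    keep = st.entry < until
    return st.entry[keep], st.duration[keep], st.weight[keep], st.covariate_matrix()[keep]


def simulate_hospital(design: StudyDesign, rep: int = 0) -> HospitalData:
    """One synthetic hospital, administratively censored at the horizon."""
    entry, duration, _, zmat = simulate_raw_stream(design, rep)
    followup = np.minimum(duration, design.horizon - entry)
    event = duration <= design.horizon - entry
    subjects = [
        SubjectRecord(
            id=f"h{rep}-s{j}",
            entry_time=float(entry[j]),
            followup_time=float(followup[j]),
            event=bool(event[j]),
            covariates=tuple(zmat[j]) if zmat.size else (),
        )
        for j in range(entry.size)
    ]
    return HospitalData(hospital_id=f"sim-{design.seed}-{rep}", subjects=subjects,
                        horizon=design.horizon)


def simulate_hospitals(design: StudyDesign) -> list[HospitalData]:
    return [simulate_hospital(design, rep) for rep in range(design.n_hospitals)]


# ---------------------------------------------------------------------------
# Chart evaluation on raw streams
# ---------------------------------------------------------------------------


def _stream_chart_values(spec: ChartSpec, model: RiskModel, st: _Stream,
                         t_lo: float, t_hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Chart values at the distinct failure times in (t_lo, t_hi]."""
    exit_ = st.exit
    ft = np.unique(exit_[(exit_ > t_lo) & (exit_ <= t_hi)])
    if ft.size == 0:
        return ft, ft
    fast_ok = isinstance(model.baseline, ExponentialBaseline)
    if spec.kind == "CGR" and fast_ok:
        log_cap = np.log(spec.mle_cap) if spec.mle_cap is not None else np.inf
        vals = _fast.cgr_values_exponential(
            st.entry, exit_, np.ones(exit_.size, dtype=bool), st.weight,
            model.baseline.rate, log_cap, ft)
        return ft, vals
    agg = AggregateProcess(st.entry, st.duration, np.ones(exit_.size, dtype=bool),
                           st.weight, model)
    if spec.kind == "CGI":
        path = cgi_chart(agg, ft, spec.mle_cap)
    elif spec.kind == "CGR":
        path = cgr_chart(agg, ft, spec.mle_cap)
    elif spec.kind == "BK":
        path = bk_chart(agg, spec.theta1, ft)
    else:
        raise ValueError(f"raw-stream evaluation does not handle {spec.kind}")
    return ft, path.values


@dataclass
class _RunRecord:
    """Running-max increments of one chart run: times and new maxima."""

    times: np.ndarray
    maxima: np.ndarray
    cap: float
    capped: bool

    def first_crossing(self, h: float) -> float | None:
        idx = np.searchsorted(self.maxima, h, side="left")
        if idx == self.maxima.size:
            return None
        return float(self.times[idx])


def _run_chart_record(spec: ChartSpec, design: StudyDesign, rep: int,
                      cap: float, stop_value: float = np.inf) -> _RunRecord:
    """Simulate one hospital until the chart running max reaches ``stop_value``.

    Advances chunk by chunk, evaluating the chart at the failure times of
    each chunk against the full accumulated history; returns the times at
    which the running maximum increased and the new maxima, truncated once
    ``stop_value`` is reached or the time cap is hit.
    """
    if spec.kind == "BERNOULLI":
        hosp = simulate_hospital(replace(design, horizon=cap), rep)
        path = bernoulli_chart(hosp, design.model, spec.theta1)
        vals, times = path.values, path.times
        rec_t, rec_m = [], []
        best = -np.inf
        for t, v in zip(times, vals):
            if v > best:
                best = v
                rec_t.append(t)
                rec_m.append(v)
                if best >= stop_value:
                    break
        return _RunRecord(np.array(rec_t), np.array(rec_m), cap,
                          capped=not (rec_m and rec_m[-1] >= stop_value))
    st = _Stream(design, rep)
    rec_t: list[float] = []
    rec_m: list[float] = []
    best = 0.0
    t_lo = 0.0
    while t_lo < cap:
        t_hi = min(t_lo + CHUNK_DAYS, cap)
        st.extend_to(t_hi)
        ft, vals = _stream_chart_values(spec, design.model, st, t_lo, t_hi)
        for t, v in zip(ft, vals):
            if v > best:
                best = float(v)
                rec_t.append(float(t))
                rec_m.append(best)
                if best >= stop_value:
                    return _RunRecord(np.array(rec_t), np.array(rec_m), cap, capped=False)
        t_lo = t_hi
    return _RunRecord(np.array(rec_t), np.array(rec_m), cap, capped=True)


def chart_run_length(spec: ChartSpec, design: StudyDesign, rep: int,
                     cap: float, h: float | None = None) -> float | None:
    """Detection time of one simulated run, or ``None`` if not signalled by ``cap``."""
    h = spec.control_limit if h is None else h
    if h is None:
        raise ValueError("a control limit is required")
    rec = _run_chart_record(spec, design, rep, cap, stop_value=h)
    return rec.first_crossing(h)


# ---------------------------------------------------------------------------
# Control-limit calibration
# ---------------------------------------------------------------------------


def _require_in_control(design: StudyDesign) -> None:
    cp = design.changepoint
    if cp.mode != "none" and cp.theta != 0.0:
        raise ValueError("calibration requires an in-control design (theta = 0)")


def calibrate_control_limit_type1(spec: ChartSpec, alpha: float, horizon: float,
                                  design: StudyDesign, n: int,
                                  rep_start: int = 0) -> float:
    """Control limit restricting the in-control signal probability over a horizon.

    h is the empirical (1 - alpha) quantile (upper order statistic) of the
    per-hospital maxima of the chart over ``[0, horizon]`` across ``n``
    simulated in-control hospitals, so the fraction of in-control hospitals
    signalling within the horizon at limit h is approximately alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    _require_in_control(design)
    maxima = np.empty(n)
    for j in range(n):
        rec = _run_chart_record(spec, design, rep_start + j, cap=horizon)
        maxima[j] = rec.maxima[-1] if rec.maxima.size else 0.0
    if np.all(maxima == 0.0):
        warnings.warn("degenerate calibration: no failures produced any chart "
                      "excursion; control limit is 0")
        return 0.0
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


@dataclass
class CalibrationResult:
    """Calibrated limit plus the Monte-Carlo evidence behind it."""

    h: float
    estimated_arl: float
    n: int
    censored: int
    cap: float

    def __float__(self) -> float:
        return self.h


def calibrate_control_limit_arl(spec: ChartSpec, target_arl: float,
                                design: StudyDesign, n: int,
                                cap: float | None = None,
                                h_bracket: tuple[float, float] | None = None,
                                rel_tol: float = 1e-6,
                                rep_start: int = 0) -> CalibrationResult:
    """Control limit whose estimated in-control ARL matches ``target_arl``.

    Simulates ``n`` in-control hospitals once, keeping each run's record of
    running-max increments up to the time cap (default ``10 * target_arl``),
    then bisects on h: the estimated ARL — the mean first crossing time, with
    runs that never cross counted at the cap — is a nondecreasing step
    function of h, so the same simulated pool serves every candidate.
    Supplying ``h_bracket`` lets runs stop early once their maximum exceeds
    the upper bracket (exact for any h inside the bracket).
    """
    if not target_arl > 0:
        raise ValueError("target_arl must be > 0")
    _require_in_control(design)
    cap = 10.0 * target_arl if cap is None else cap
    stop = h_bracket[1] if h_bracket is not None else np.inf
    pool = [_run_chart_record(spec, design, rep_start + j, cap=cap, stop_value=stop)
            for j in range(n)]

    def est_arl(h: float) -> tuple[float, int]:
        taus = np.array([rec.first_crossing(h) or cap for rec in pool])
        censored = int(sum(rec.first_crossing(h) is None for rec in pool))
        return float(np.mean(taus)), censored

    if h_bracket is not None:
        lo, hi = h_bracket
    else:
        finals = [rec.maxima[-1] for rec in pool if rec.maxima.size]
        if not finals:
            raise RuntimeError("no chart excursions: cannot calibrate")
        lo, hi = 1e-9, float(max(finals))
    arl_lo, _ = est_arl(lo)
    arl_hi, _ = est_arl(hi)
    if not arl_lo <= arl_hi:  # monotone search premise
        raise AssertionError("estimated ARL must be nondecreasing in h")
    if arl_hi < target_arl:
        raise RuntimeError(
            f"target ARL {target_arl} not reachable below h={hi} "
            f"(estimated ARL there: {arl_hi}); raise the cap or bracket"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if est_arl(mid)[0] < target_arl:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rel_tol * max(hi, 1.0):
            break
    est, censored = est_arl(hi)
    return CalibrationResult(h=float(hi), estimated_arl=est, n=n,
                             censored=censored, cap=cap)


# ---------------------------------------------------------------------------
# Run-length and power studies
# ---------------------------------------------------------------------------


def _chart_label(spec: ChartSpec) -> str:
    bits = [spec.kind]
    if spec.theta1 is not None:
        bits.append(f"exp(theta1)={math.exp(spec.theta1):g}")
    if spec.mle_cap is not None:
        bits.append(f"cap={spec.mle_cap:g}")
    return " ".join(bits)


def run_length_study(charts: list[ChartSpec], hazard_ratios, design: StudyDesign,
                     n: int, cap: float = 40 * DAYS_PER_YEAR,
                     cgr_as_cgi_out_of_control: bool = True) -> pd.DataFrame:
    """Mean/SD/median detection times per chart and hazard ratio.

    Out-of-control data raise the hazard from the start of the study for
    every subject.  For out-of-control rows a CGR spec is evaluated as the
    CGI chart: pathwise CGR >= CGI, so the CGI run lengths upper-bound the
    CGR run lengths while avoiding the suffix scan; in-control rows run the
    CGR chart itself.  Summary statistics are computed over the runs that
    signalled within the ``cap``; runs still silent at the cap are reported
    in the ``censored`` column (they are common for in-control rows, where
    the run-length distribution is extremely right-skewed).
    """
    rows = []
    for spec in charts:
        if spec.control_limit is None:
            raise ValueError(f"chart {_chart_label(spec)} has no control limit")
        for ehr in hazard_ratios:
            theta = math.log(ehr)
            if theta == 0.0:
                d = replace(design, changepoint=ChangepointSpec())
                eff = spec
            else:
                d = replace(design, changepoint=ChangepointSpec("from_start", theta=theta))
                eff = (replace_kind(spec, "CGI")
                       if spec.kind == "CGR" and cgr_as_cgi_out_of_control else spec)
            taus = []
            censored = 0
            for rep in range(n):
                tau = chart_run_length(eff, d, rep, cap)
                if tau is None:
                    censored += 1
                else:
                    taus.append(tau)
            taus = np.asarray(taus, dtype=float)
            rows.append({
                "chart": _chart_label(spec),
                "hazard_ratio": ehr,
                "arl": float(np.mean(taus)) if taus.size else float("nan"),
                "sd": float(np.std(taus, ddof=1)) if taus.size > 1 else float("nan"),
                "mrl": float(np.median(taus)) if taus.size else float("nan"),
                "n": n,
                "censored": censored,
            })
    return pd.DataFrame(rows, columns=["chart", "hazard_ratio", "arl", "sd",
                                       "mrl", "n", "censored"])


def replace_kind(spec: ChartSpec, kind: str) -> ChartSpec:
    """Same chart parameters under a different kind (CGR <-> CGI)."""
    return ChartSpec(kind=kind, theta1=spec.theta1, mle_cap=spec.mle_cap,
                     control_limit=spec.control_limit)


def power_study(charts: list[ChartSpec], psis, theta: float, horizon: float,
                design: StudyDesign, n: int, alpha: float = 0.1,
                grid_step: float = 30.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Power over time under a common in-control type-I-error restriction.

    Per chart and arrival rate psi: calibrate h so that the in-control
    signal probability over the horizon is ~alpha (on ``n`` hospitals), then
    simulate ``n`` out-of-control hospitals (hazard raised by exp(theta)
    from the start) and report the empirical fraction signalled by each grid
    time, plus the realized in-control fraction on a fresh sample.
    """
    curves = []
    summary = []
    grid = np.arange(grid_step, horizon + grid_step * 1e-9, grid_step)
    for psi in psis:
        base = replace(design, psi=psi, changepoint=ChangepointSpec(), horizon=horizon)
        ooc = replace(base, changepoint=ChangepointSpec("from_start", theta=theta))
        for spec in charts:
            h = calibrate_control_limit_type1(spec, alpha, horizon, base, n)
            taus = np.array([chart_run_length(spec, ooc, rep, cap=horizon, h=h) or np.inf
                             for rep in range(n)])
            fresh = np.array([chart_run_length(spec, base, n + rep, cap=horizon, h=h) or np.inf
                              for rep in range(n)])
            realized = float(np.mean(np.isfinite(fresh)))
            for t in grid:
                curves.append({"chart": _chart_label(spec), "psi": psi,
                               "time": float(t), "power": float(np.mean(taus <= t))})
            summary.append({"chart": _chart_label(spec), "psi": psi, "h": h,
                            "realized_type1": realized, "n": n})
    return (pd.DataFrame(curves, columns=["chart", "psi", "time", "power"]),
            pd.DataFrame(summary, columns=["chart", "psi", "h", "realized_type1", "n"]))
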