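"""Core domain types: subjects, risk models, and aggregated counting processes.

The monitoring problem: subjects enter a center over calendar time, each
carries a known null distribution for its time-to-event (a baseline
cumulative hazard, optionally risk-adjusted by a Cox linear predictor
``exp(Z'beta)``).  Charts compare the observed failure counting process
``N(t)`` against the model-implied cumulative intensity ``Lambda(t)``.

Time is measured in days from the start of monitoring (``t = 0``); subject
time is ``x = t - S_i`` where ``S_i`` is the subject's entry time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CovariateDimensionError",
    "UnboundedMLEError",
    "ExponentialBaseline",
    "WeibullBaseline",
    "StepBaseline",
    "RiskModel",
    "SubjectRecord",
    "HospitalData",
    "AggregateProcess",
    "subject_cumulative_intensity",
    "aggregate_processes",
    "theta_hat",
]


class CovariateDimensionError(ValueError):
    """Covariate vector length does not match the coefficient vector."""


class UnboundedMLEError(ValueError):
    """The hazard-ratio MLE is unbounded (events with zero cumulative intensity).

    Occurs when a failure is observed while the model-implied cumulative
    intensity is exactly zero, e.g. a step baseline that is flat at zero in a
    neighbourhood of entry.  Charts require either an MLE cap or a baseline
    with strictly positive cumulative hazard away from zero.
    """


# ---------------------------------------------------------------------------
# Baseline cumulative hazards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialBaseline:
    """Constant baseline hazard ``h0(x) = rate`` (per day), ``H0(x) = rate * x``."""

    rate: float

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("exponential baseline requires rate > 0")

    def cumulative_hazard(self, x):
        return self.rate * np.asarray(x, dtype=float)

    def inverse_cumulative_hazard(self, u):
        return np.asarray(u, dtype=float) / self.rate


@dataclass(frozen=True)
class WeibullBaseline:
    """Weibull baseline, ``H0(x) = (x / scale) ** shape``."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("weibull baseline requires shape > 0 and scale > 0")

    def cumulative_hazard(self, x):
        return (np.asarray(x, dtype=float) / self.scale) ** self.shape

    def inverse_cumulative_hazard(self, u):
        return self.scale * np.asarray(u, dtype=float) ** (1.0 / self.shape)


@dataclass(frozen=True)
class StepBaseline:
    """Tabulated cumulative hazard, linearly interpolated between knots.

    Beyond the last knot the cumulative hazard is extrapolated linearly at
    the slope of the last inter-knot segment (i.e. a constant hazard equal to
    that of the last segment).  ``H0(0) = 0`` is required.
    """

    knots: tuple
    values: tuple

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if k.ndim != 1 or k.shape != v.shape or k.size < 2:
            raise ValueError("step baseline needs matching 1-d knots/values, >= 2 knots")
        if k[0] != 0.0 or v[0] != 0.0:
            raise ValueError("step baseline must start at H0(0) = 0")
        if np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(np.diff(v) < 0):
            raise ValueError("cumulative hazard values must be nondecreasing")
        object.__setattr__(self, "knots", tuple(k))
        object.__setattr__(self, "values", tuple(v))

    def _arrays(self):
        return np.asarray(self.knots), np.asarray(self.values)

    def cumulative_hazard(self, x):
        k, v = self._arrays()
        x = np.asarray(x, dtype=float)
        slope = (v[-1] - v[-2]) / (k[-1] - k[-2])
        out = np.interp(x, k, v)
        beyond = x > k[-1]
        out = np.where(beyond, v[-1] + slope * (x - k[-1]), out)
        return out

    def inverse_cumulative_hazard(self, u):
        k, v = self._arrays()
        u = np.asarray(u, dtype=float)
        if np.any(np.diff(v) == 0) and np.any(u > 0):
            # flat segments: np.interp picks the left edge, which is the
            # infimum convention for the generalized inverse
            pass
        slope = (v[-1] - v[-2]) / (k[-1] - k[-2])
        if slope <= 0:
            slope = np.nan  # cannot invert beyond a flat tail
        out = np.interp(u, v, k)
        beyond = u > v[-1]
        out = np.where(beyond, k[-1] + (u - v[-1]) / slope, out)
        return out


Baseline = ExponentialBaseline | WeibullBaseline | StepBaseline


# ---------------------------------------------------------------------------
# Risk model and subject records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskModel:
    """Null (in-control) failure model: baseline hazard plus Cox coefficients.

    A subject with covariates ``Z`` has cumulative hazard
    ``exp(Z' beta) * H0(x)`` at ``x`` days after entry; under a hazard ratio
    ``exp(theta)`` its failure CDF is ``1 - exp(-exp(theta) exp(Z'beta) H0(x))``.
    """

    baseline: Baseline
    coefficients: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(b) for b in self.coefficients))

    def linear_predictor_weight(self, covariates) -> float:
        """``exp(Z' beta)`` for one covariate vector."""
        z = np.asarray(covariates, dtype=float)
        beta = np.asarray(self.coefficients, dtype=float)
        if z.shape != beta.shape:
            raise CovariateDimensionError(
                f"covariate vector of length {z.size} does not match "
                f"{beta.size} coefficients"
            )
        return float(np.exp(z @ beta)) if beta.size else 1.0

    def weights(self, covariate_matrix: np.ndarray) -> np.ndarray:
        """Vector of ``exp(Z' beta)`` for an (n, p) covariate matrix."""
        beta = np.asarray(self.coefficients, dtype=float)
        zmat = np.asarray(covariate_matrix, dtype=float)
        if beta.size == 0:
            return np.ones(zmat.shape[0] if zmat.ndim else 0)
        if zmat.ndim != 2 or zmat.shape[1] != beta.size:
            raise CovariateDimensionError(
                f"covariate matrix with {zmat.shape} shape does not match "
                f"{beta.size} coefficients"
            )
        return np.exp(zmat @ beta)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: entry time ``S_i``, follow-up, event flag, covariates.

    ``followup_time`` is the observed time on study (``min(X_i, R_i - S_i)``);
    when ``event`` is true the failure occurred at
    ``entry_time + followup_time`` and it is the subject's only counted event.
    """

    id: str
    entry_time: float
    followup_time: float
    event: bool
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if self.entry_time < 0:
            raise ValueError(f"subject {self.id}: entry_time must be >= 0")
        if not self.followup_time > 0:
            raise ValueError(f"subject {self.id}: followup_time must be > 0")
        object.__setattr__(self, "covariates", tuple(float(z) for z in self.covariates))

    @property
    def exit_time(self) -> float:
        """Chronological time of failure or censoring."""
        return self.entry_time + self.followup_time


@dataclass
class HospitalData:
    """All subjects of one center, sorted by entry time (stable for ties)."""

    hospital_id: str
    subjects: list
    horizon: float

    def __post_init__(self) -> None:
        self.subjects = sorted(self.subjects, key=lambda s: s.entry_time)
        for s in self.subjects:
            if s.entry_time > self.horizon:
                raise ValueError(
                    f"subject {s.id} enters at {s.entry_time} after horizon {self.horizon}"
                )

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# Per-subject and aggregated intensities
# ---------------------------------------------------------------------------


def subject_cumulative_intensity(subject: SubjectRecord, model: RiskModel, t: float) -> float:
    """Cumulative intensity ``Lambda_i(t)`` of one subject at calendar time t.

    Equals ``exp(Z'beta) * H0(clamp(t - S_i, 0, followup))``: zero before
    entry, frozen after exit (failure or censoring) — exactly the integral of
    the at-risk indicator times the subject's hazard.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    w = model.linear_predictor_weight(subject.covariates)
    x = min(max(t - subject.entry_time, 0.0), subject.followup_time)
    return float(w * model.baseline.cumulative_hazard(x))


class AggregateProcess:
    """Counting process ``N`` and cumulative intensity ``Lambda`` of a center.

    Stores per-subject arrays sorted by entry time so that the suffix sums
    ``N_{>=nu}(t)`` and ``Lambda_{>=nu}(t)`` (subjects nu, nu+1, ... in entry
    order) used by the generalized charts are available for any nu.
    """

    def __init__(self, entry, followup, event, weight, model: RiskModel,
                 hospital_id: str = ""):
        entry = np.asarray(entry, dtype=float)
        order = np.argsort(entry, kind="stable")
        self.entry = entry[order]
        self.followup = np.asarray(followup, dtype=float)[order]
        self.event = np.asarray(event, dtype=bool)[order]
        self.weight = np.asarray(weight, dtype=float)[order]
        self.model = model
        self.hospital_id = hospital_id
        self.exit = self.entry + self.followup
        ft = self.exit[self.event]
        self.failure_times = np.sort(ft)
        # sorted copies + prefix sums back the O(log n) Lambda evaluation for
        # constant-hazard baselines
        if isinstance(model.baseline, ExponentialBaseline):
            self._s_sorted = self.entry  # already sorted by entry
            self._s_wsort = self.weight
            ex_order = np.argsort(self.exit, kind="stable")
            self._e_sorted = self.exit[ex_order]
            self._e_wsort = self.weight[ex_order]
            self._s_cw = np.concatenate([[0.0], np.cumsum(self._s_wsort)])
            self._s_cwa = np.concatenate([[0.0], np.cumsum(self._s_wsort * self._s_sorted)])
            self._e_cw = np.concatenate([[0.0], np.cumsum(self._e_wsort)])
            self._e_cwa = np.concatenate([[0.0], np.cumsum(self._e_wsort * self._e_sorted)])
            self._total_w = float(np.sum(self.weight))

    # -- construction -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.entry.size

    # -- pointwise evaluation ----------------------------------------------

    def n_at(self, times) -> np.ndarray:
        """Number of observed failures ``N(t)`` at each time."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        return np.searchsorted(self.failure_times, t, side="right").astype(float)

    def _sum_w_min(self, cum_w, cum_wa, sorted_a, times):
        # sum_i w_i * min(t, a_i) via prefix sums over the sorted a's
        idx = np.searchsorted(sorted_a, times, side="right")
        return cum_wa[idx] + times * (self._total_w - cum_w[idx])

    def lambda_at(self, times) -> np.ndarray:
        """Total cumulative intensity ``Lambda(t)`` at each time."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if self.n_subjects == 0:
            return np.zeros_like(t)
        if isinstance(self.model.baseline, ExponentialBaseline):
            lam = self.model.baseline.rate
            return lam * (
                self._sum_w_min(self._e_cw, self._e_cwa, self._e_sorted, t)
                - self._sum_w_min(self._s_cw, self._s_cwa, self._s_sorted, t)
            )
        # generic baselines: chunked broadcast of the closed per-subject form
        out = np.empty(t.size)
        chunk = max(1, int(4_000_000 // max(self.n_subjects, 1)))
        for lo in range(0, t.size, chunk):
            tt = t[lo:lo + chunk, None]
            x = np.clip(tt - self.entry[None, :], 0.0, self.followup[None, :])
            out[lo:lo + chunk] = (self.weight[None, :]
                                  * self.model.baseline.cumulative_hazard(x)).sum(axis=1)
        return out

    def per_subject_lambda_at(self, t: float) -> np.ndarray:
        """Vector of ``Lambda_i(t)`` in entry order."""
        x = np.clip(t - self.entry, 0.0, self.followup)
        return self.weight * np.asarray(self.model.baseline.cumulative_hazard(x))

    def per_subject_n_at(self, t: float) -> np.ndarray:
        """Vector of ``N_i(t)`` (0/1) in entry order."""
        return (self.event & (self.exit <= t)).astype(float)

    def suffix_n_at(self, t: float) -> np.ndarray:
        """``N_{>=nu}(t)`` for nu = 1..n+1 (last element is the empty suffix)."""
        n_i = self.per_subject_n_at(t)
        out = np.zeros(self.n_subjects + 1)
        out[:-1] = np.cumsum(n_i[::-1])[::-1]
        return out

    def suffix_lambda_at(self, t: float) -> np.ndarray:
        """``Lambda_{>=nu}(t)`` for nu = 1..n+1 (last element is the empty suffix)."""
        lam_i = self.per_subject_lambda_at(t)
        out = np.zeros(self.n_subjects + 1)
        out[:-1] = np.cumsum(lam_i[::-1])[::-1]
        return out


def aggregate_processes(hospital: HospitalData, model: RiskModel) -> AggregateProcess:
    """Build the aggregated counting/intensity process for one center."""
    n = len(hospital.subjects)
    entry = np.array([s.entry_time for s in hospital.subjects], dtype=float)
    followup = np.array([s.followup_time for s in hospital.subjects], dtype=float)
    event = np.array([s.event for s in hospital.subjects], dtype=bool)
    if n and len(hospital.subjects[0].covariates):
        zmat = np.array([s.covariates for s in hospital.subjects], dtype=float)
        weight = model.weights(zmat)
    else:
        if model.coefficients:
            raise CovariateDimensionError(
                "model has coefficients but subjects carry no covariates"
            )
        weight = np.ones(n)
    return AggregateProcess(entry, followup, event, weight, model,
                            hospital_id=hospital.hospital_id)


# ---------------------------------------------------------------------------
# Hazard-ratio MLE
# ---------------------------------------------------------------------------


def theta_hat(n: float, lam: float, cap: float | None = None) -> float:
    """MLE of the log hazard ratio given N failures and cumulative intensity.

    ``max(0, log(N / Lambda))``, optionally bounded above by ``log(cap)``
    (a restriction on the estimated hazard ratio itself).  ``Lambda = 0``
    with ``N > 0`` is an unbounded MLE: returns ``log(cap)`` when capped,
    raises otherwise.
    """
    if n < 0:
        raise ValueError("N must be >= 0")
    if lam < 0:
        raise ValueError("Lambda must be >= 0")
    if cap is not None and not cap > 1:
        raise ValueError("cap must be a hazard ratio > 1")
    if lam == 0.0:
        if n == 0:
            return 0.0
        if cap is None:
            raise UnboundedMLEError(
                "failure observed with zero cumulative intensity and no MLE cap"
            )
        return math.log(cap)
    if n == 0:
        return 0.0
    th = max(0.0, math.log(n / lam))
    if cap is not None:
        th = min(th, math.log(cap))
    return th
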