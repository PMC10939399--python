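"""Compiled inner loop for the CGR suffix scan on constant-hazard streams.

The CGR statistic has no recursion over time: every evaluation rescans all
suffixes of the subjects in entry order.  For long in-control simulations
(tens of thousands of events) that scan dominates the run time, so it is
compiled with numba when available; a vectorized numpy fallback with the
same contract is kept for environments without a JIT and as a cross-check.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _cgr_values_exponential_py(entry, exit_, is_event, weight, rate, log_cap, times):
    out = np.empty(times.size)
    for j in range(times.size):
        t = times[j]
        lam_i = weight * rate * np.clip(np.minimum(t, exit_) - entry, 0.0, None)
        n_i = (is_event & (exit_ <= t)).astype(float)
        suf_l = np.cumsum(lam_i[::-1])
        suf_n = np.cumsum(n_i[::-1])
        pos = suf_n > suf_l
        best = 0.0
        if np.any(pos):
            with np.errstate(divide="ignore"):
                th = np.minimum(np.log(suf_n[pos] / suf_l[pos]), log_cap)
            best = float(np.max(th * suf_n[pos] - np.expm1(th) * suf_l[pos]))
        out[j] = max(best, 0.0)
    return out


def _kernel(entry, exit_, is_event, weight, rate, log_cap, times):
    n = entry.size
    out = np.empty(times.size)
    for j in range(times.size):
        t = times[j]
        best = 0.0
        suf_n = 0.0
        suf_l = 0.0
        for i in range(n - 1, -1, -1):
            if entry[i] >= t:
                continue
            x = t - entry[i]
            d = exit_[i] - entry[i]
            if d < x:
                x = d
            suf_l += weight[i] * rate * x
            if is_event[i] and exit_[i] <= t:
                suf_n += 1.0
            if suf_n > suf_l:
                th = np.log(suf_n / suf_l)
                if th > log_cap:
                    th = log_cap
                v = th * suf_n - (np.exp(th) - 1.0) * suf_l
                if v > best:
                    best = v
        out[j] = best
    return out


if njit is not None:
    _cgr_values_exponential_nb = njit(cache=True, nogil=True)(_kernel)
else:  # pragma: no cover
    _cgr_values_exponential_nb = None


def cgr_values_exponential(entry, exit_, is_event, weight, rate, log_cap, times):
    """CGR chart values at ``times`` for an exponential-baseline stream.

    ``entry`` must be sorted ascending; ``exit_`` is entry + follow-up;
    ``is_event`` marks observed failures.  ``log_cap`` may be ``np.inf``.
    The exponential baseline guarantees every suffix with a failure has
    positive cumulative intensity, so no MLE cap is required here.
    """
    entry = np.ascontiguousarray(entry, dtype=np.float64)
    exit_ = np.ascontiguousarray(exit_, dtype=np.float64)
    is_event = np.ascontiguousarray(is_event, dtype=np.bool_)
    weight = np.ascontiguousarray(weight, dtype=np.float64)
    times = np.ascontiguousarray(times, dtype=np.float64)
    if _cgr_values_exponential_nb is not None:
        return _cgr_values_exponential_nb(entry, exit_, is_event, weight,
                                          float(rate), float(log_cap), times)
    return _cgr_values_exponential_py(entry, exit_, is_event, weight,
                                      float(rate), float(log_cap), times)
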