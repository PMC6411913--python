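"""Inversion of the capped-brood balance for piecewise-constant capping rates.

The total capped brood observed at time ``t`` is the survival-weighted
integral of the capping rate over the preceding pupal window::

    b(t) = integral_0^{T_pupa} u(t - s) * p(t - s)^(s / T_pupa) ds

where ``u`` is the daily capping rate and ``p`` the eclosion probability of
the cohort capped at ``t - s`` (the fractional exponent encodes the
assumption that a dead pupa is removed from its cell immediately, so
in-cell attrition accrues continuously over the pupal period).  With ``u``
and ``p`` constant between consecutive censuses, evaluating the balance at
every census date yields a lower-triangular linear system in the interval
rates, solved exactly by forward substitution.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .core import (
    RATE_NEGATIVE_CLAMPED,
    RATE_OK,
    CappingRateSeries,
    CensusSeries,
    ColonyParams,
    InconsistentCensusError,
    ValidationError,
)

__all__ = [
    "survival_weight_integral",
    "build_capping_system",
    "solve_capping_rates",
]

#: Rates smaller than this fraction of the largest rate magnitude are
#: snapped to zero before the sign check.
SNAP_RTOL = 1e-9


def survival_weight_integral(s1: float, s2: float, p: float, t_pupa: float) -> float:
    """Integral of the in-cell survival weight ``p**(s/t_pupa)`` over ``[s1, s2]``.

    This is the closed-form kernel weight
    ``(t_pupa/ln p) * (p**(s2/t_pupa) - p**(s1/t_pupa))``, reducing to
    ``s2 - s1`` as ``p -> 1``.  Ages are measured since capping and must
    satisfy ``0 <= s1 <= s2 <= t_pupa``.
    """
    if not (0.0 <= s1 <= s2 <= t_pupa):
        raise ValidationError(
            f"ages must satisfy 0 <= s1 <= s2 <= t_pupa, got ({s1}, {s2}, {t_pupa})"
        )
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"eclosion rate must lie in (0, 1], got {p}")
    c = math.log(p) / t_pupa
    if c == 0.0:
        return s2 - s1
    # expm1 keeps precision as p -> 1, where the direct difference of
    # powers cancels catastrophically
    return math.exp(c * s1) * math.expm1(c * (s2 - s1)) / c


def _kernel_matrix(times: np.ndarray, p_vec: np.ndarray, t_pupa: float) -> np.ndarray:
    """Lower-triangular matrix mapping interval rates to brood counts.

    Row ``k`` integrates the survival weight over the part of the age range
    ``s in [0, t_pupa]`` for which the capping time ``t_k - s`` falls in
    interval ``j`` (interval 0 is the unbounded pre-experiment band
    ``t < t_0``; interval ``j >= 1`` is ``[t_{j-1}, t_j)``).
    """
    n = times.size
    mat = np.zeros((n, n))
    for k in range(n):
        t_k = times[k]
        tau_min = t_k - t_pupa
        for j in range(k + 1):
            lo = -np.inf if j == 0 else times[j - 1]
            hi = times[0] if j == 0 else times[j]
            ov_lo = max(lo, tau_min)
            ov_hi = min(hi, t_k)
            if ov_hi <= ov_lo:
                continue
            # map capping times back to ages since capping
            s1, s2 = t_k - ov_hi, t_k - ov_lo
            mat[k, j] = survival_weight_integral(s1, s2, p_vec[j], t_pupa)
    return mat


def build_capping_system(
    census: CensusSeries,
    params: ColonyParams,
    initial_brood: str = "integral",
) -> Tuple[np.ndarray, np.ndarray]:
    """Assemble the linear system ``A @ rates = brood_counts``.

    ``A`` is N x N lower triangular with positive diagonal; row ``k``'s
    coefficients sum to the full-window weight
    ``survival_weight_integral(0, t_pupa, p, t_pupa)`` (for scalar ``p``).

    ``initial_brood`` selects how the first row anchors the pre-experiment
    history: ``"integral"`` (default) applies the survival-weighted kernel
    to a constant historical rate, while ``"uniform"`` assumes the initial
    capped brood is uniformly distributed over age so that
    ``rates[0] = b(t_0) / t_pupa``.
    """
    if initial_brood not in ("integral", "uniform"):
        raise ValidationError(
            f"initial_brood must be 'integral' or 'uniform', got {initial_brood!r}"
        )
    times = census.times()
    p_vec = params.eclosion_vector(census.n)
    mat = _kernel_matrix(times, p_vec, params.t_pupa)
    if initial_brood == "uniform":
        mat[0, :] = 0.0
        mat[0, 0] = params.t_pupa
    return mat, census.brood_counts.copy()


def _forward_substitution(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    n = rhs.size
    out = np.empty(n)
    for k in range(n):
        out[k] = (rhs[k] - mat[k, :k] @ out[:k]) / mat[k, k]
    return out


def _interval_label(series_dates, j: int) -> str:
    if j == 0:
        return f"pre-history (t < {series_dates[0]})"
    return f"[{series_dates[j - 1]}, {series_dates[j]})"


def solve_capping_rates(
    census: CensusSeries,
    params: ColonyParams,
    negative_policy: str = "error",
    initial_brood: str = "integral",
) -> CappingRateSeries:
    """Solve for the per-interval capping rates from the brood counts.

    The system is lower triangular with strictly positive diagonal, so the
    solution is unique.  A negative rate signals mutually inconsistent
    counts; under ``negative_policy="error"`` (default) an
    :class:`InconsistentCensusError` names the offending interval(s), while
    ``"clamp_warn"`` clamps each negative rate to zero, re-solves the
    subsequent rows with the clamped value, and flags those intervals.
    """
    if negative_policy not in ("error", "clamp_warn"):
        raise ValidationError(
            f"negative_policy must be 'error' or 'clamp_warn', got {negative_policy!r}"
        )
    mat, rhs = build_capping_system(census, params, initial_brood=initial_brood)
    raw = _forward_substitution(mat, rhs)
    snap = SNAP_RTOL * float(np.max(np.abs(raw))) if raw.size else 0.0
    raw[np.abs(raw) < snap] = 0.0

    negative = np.flatnonzero(raw < 0)
    if negative.size == 0:
        return CappingRateSeries(breakpoints=census.dates, rates=raw)

    if negative_policy == "error":
        labels = ", ".join(_interval_label(census.dates, int(j)) for j in negative)
        raise InconsistentCensusError(
            "adult-bee and capped-brood counts are inconsistent: negative "
            f"capping rate in interval(s) {labels}; the apparent longevity "
            "cannot be obtained because the rate equations have no "
            "nonnegative solution",
            intervals=[int(j) for j in negative],
        )

    # clamp_warn: sequential re-solve so each clamped value feeds the rows below
    n = rhs.size
    rates = np.empty(n)
    flags = []
    for k in range(n):
        val = (rhs[k] - mat[k, :k] @ rates[:k]) / mat[k, k]
        if abs(val) < snap:
            val = 0.0
        if val < 0:
            rates[k] = 0.0
            flags.append(RATE_NEGATIVE_CLAMPED)
        else:
            rates[k] = val
            flags.append(RATE_OK)
    return CappingRateSeries(breakpoints=census.dates, rates=rates, flags=flags)
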