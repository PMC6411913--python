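"""Inversion of the adult-population balance for the apparent longevity L(t).

The adult bees present at time ``t`` are the cohorts that have emerged
(age since capping beyond the pupal period) but not yet reached the
"border" age at which an average worker disappears from the colony::

    a(t) = integral_{T_pupa}^{T_pupa + L(t)} u(t - s) * p(t - s) ds

Apparent longevity lumps every way a worker leaves — death, predation,
failure to return — into a single age limit.  With piecewise-constant
``u`` and ``p`` the cumulative-emergence function G(L) is continuous,
piecewise linear and nondecreasing, so L is found exactly by walking the
capping intervals backward in time and interpolating inside the final
interval; no iteration or tolerance is involved.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Optional, Tuple

import numpy as np

from .core import (
    STATUS_COLLAPSED,
    STATUS_INCONSISTENT,
    STATUS_NO_SOLUTION,
    STATUS_OK,
    CappingRateSeries,
    CensusSeries,
    ColonyParams,
    DateLike,
    LongevitySeries,
    ValidationError,
    as_day_value,
)
from .capping import solve_capping_rates

__all__ = [
    "cumulative_emergence",
    "apparent_longevity_at",
    "compute_longevity_series",
    "DEFAULT_LONGEVITY_CAP",
]

#: Hard cap on the longevity search (days); guards against a zero
#: pre-history rate making G(L) bounded.
DEFAULT_LONGEVITY_CAP = 1e4


def _effective_rates(rates: CappingRateSeries, params: ColonyParams) -> np.ndarray:
    """Per-interval emergence rates u_j * p_j (adults emerging per day)."""
    r = np.asarray(rates.rates, dtype=float)
    p = params.eclosion_vector(rates.n)
    return r * p


def _query_time(t_k: DateLike, rates: CappingRateSeries) -> float:
    return as_day_value(t_k, rates.breakpoints[0])


def cumulative_emergence(
    t_k: DateLike,
    L: float,
    rates: CappingRateSeries,
    params: ColonyParams,
) -> float:
    """Adults emerged during the ``L`` days up to ``t_k - t_pupa``.

    This is G(L), the candidate adult population for longevity ``L``:
    the sum over capping intervals intersecting
    ``[t_k - t_pupa - L, t_k - t_pupa]`` of rate x eclosion x overlap.
    G(0) = 0; G is continuous, piecewise linear and nondecreasing in L.
    """
    if L < 0:
        raise ValidationError(f"longevity must be nonnegative, got {L}")
    tq = _query_time(t_k, rates)
    pts = rates.times()
    rp = _effective_rates(rates, params)
    hi = tq - params.t_pupa
    if hi > pts[-1]:
        raise ValidationError(
            f"query time {t_k!r} needs capping rates beyond the last breakpoint"
        )
    lo = hi - L
    total = 0.0
    for j in range(rates.n):
        seg_lo = -np.inf if j == 0 else pts[j - 1]
        seg_hi = pts[0] if j == 0 else pts[j]
        overlap = min(seg_hi, hi) - max(seg_lo, lo)
        if overlap > 0:
            total += rp[j] * overlap
    return total


def apparent_longevity_at(
    t_k: DateLike,
    a_k: float,
    rates: CappingRateSeries,
    params: ColonyParams,
    cap: float = DEFAULT_LONGEVITY_CAP,
) -> Tuple[float, str]:
    """Smallest L >= 0 with ``cumulative_emergence(t_k, L) == a_k``, plus status.

    Walks the capping intervals backward from ``t_k - t_pupa`` and
    linearly interpolates inside the interval where the accumulated
    emergence first reaches ``a_k``.  When the root falls on a zero-rate
    plateau the smallest L on the plateau is returned.  Status is
    ``collapsed`` for ``a_k == 0`` (L = 0 by definition), ``no_solution``
    when the total emergence supply stays below ``a_k`` (possible only
    when the history rate is zero or the ``cap`` is hit), and
    ``inconsistent_input`` when any rate is negative.
    """
    if a_k < 0:
        raise ValidationError(f"adult count must be nonnegative, got {a_k}")
    if np.any(np.asarray(rates.rates) < 0):
        return float("nan"), STATUS_INCONSISTENT
    if a_k == 0:
        return 0.0, STATUS_COLLAPSED

    pts = list(rates.times())
    rp = _effective_rates(rates, params)
    tau = _query_time(t_k, rates) - params.t_pupa
    if tau > pts[-1]:
        raise ValidationError(
            f"query time {t_k!r} needs capping rates beyond the last breakpoint"
        )
    acc = 0.0
    L = 0.0
    while True:
        remaining = a_k - acc
        if remaining <= 0.0:
            return L, STATUS_OK
        if L >= cap:
            return cap, STATUS_NO_SOLUTION
        # interval index whose rate applies just below tau:
        # tau <= t_0 -> pre-history (0); tau in (t_{m-1}, t_m] -> m
        j = bisect_left(pts, tau)
        if j == 0:
            # unbounded history band at constant rate
            if rp[0] <= 0.0:
                return L, STATUS_NO_SOLUTION
            L_final = L + remaining / rp[0]
            if L_final > cap:
                return cap, STATUS_NO_SOLUTION
            return L_final, STATUS_OK
        seg_len = tau - pts[j - 1]
        contrib = rp[j] * seg_len
        if rp[j] > 0.0 and contrib >= remaining:
            return L + remaining / rp[j], STATUS_OK
        acc += contrib
        L += seg_len
        tau = pts[j - 1]


def compute_longevity_series(
    census: CensusSeries,
    params: Optional[ColonyParams] = None,
    negative_policy: str = "error",
    initial_brood: str = "integral",
    cap: float = DEFAULT_LONGEVITY_CAP,
) -> LongevitySeries:
    """Estimate apparent longevity at every census date.

    Composes the capping-rate solve with the longevity inversion; the
    result is deterministic for fixed input.  Capping-solver
    inconsistencies propagate per ``negative_policy``.
    """
    if params is None:
        params = ColonyParams()
    rates = solve_capping_rates(
        census, params, negative_policy=negative_policy, initial_brood=initial_brood
    )
    values = np.empty(census.n)
    statuses = []
    for k in range(census.n):
        L, status = apparent_longevity_at(
            census.dates[k], float(census.adult_counts[k]), rates, params, cap=cap
        )
        values[k] = L
        statuses.append(status)
    return LongevitySeries(
        dates=census.dates, longevity=values, status=statuses, colony=census.colony
    )
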