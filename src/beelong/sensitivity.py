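"""Miscount-sensitivity experiment: perturb counts over a window, recompute L.

Field censuses miscount: weighing instead of direct counting, or counting
after foragers have left, inflates or deflates either count by tens of
percent.  Because the longevity estimate doubles as a consistency check on
the census, it is worth knowing how a windowed multiplicative miscount of
adult bees or capped brood propagates into L(t).  The characteristic
structure: adult-count errors distort L only at census dates inside the
miscounted window, while brood-count errors feed the inferred capping
rates and keep distorting L well after the window closes.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .core import (
    CaseResult,
    CensusSeries,
    ColonyParams,
    InconsistentCensusError,
    LongevitySeries,
    MiscountSpec,
    SensitivityReport,
    ValidationError,
    as_day_value,
)
from .longevity import compute_longevity_series

__all__ = ["apply_miscount", "relative_errors", "sensitivity_report"]


def _window_mask(census: CensusSeries, spec: MiscountSpec) -> np.ndarray:
    offs = np.array(
        [as_day_value(d, spec.window_start) for d in census.dates], dtype=float
    )
    width = as_day_value(spec.window_end, spec.window_start)
    return (offs >= 0) & (offs <= width)  # both endpoints inclusive


def apply_miscount(
    census: CensusSeries, spec: MiscountSpec, round_counts: bool = False
) -> CensusSeries:
    """Multiply the targeted counts by ``spec.factor`` inside the window.

    Census dates outside ``[window_start, window_end]`` (inclusive) and the
    untargeted count kind are untouched; the input series is never
    modified.  ``round_counts`` rounds the perturbed values to integers for
    count realism; by default they stay real-valued since the model is
    continuous.  A window containing no census date warns and returns an
    unperturbed copy.
    """
    mask = _window_mask(census, spec)
    if not mask.any():
        warnings.warn(
            f"miscount window [{spec.window_start}, {spec.window_end}] contains "
            "no census date; returning the census unchanged",
            stacklevel=2,
        )
        return census.with_counts()
    counts = (
        census.adult_counts if spec.target == "adult" else census.brood_counts
    ).copy()
    counts[mask] *= spec.factor
    if round_counts:
        counts[mask] = np.round(counts[mask])
    if spec.target == "adult":
        return census.with_counts(adult=counts)
    return census.with_counts(brood=counts)


def relative_errors(
    original: LongevitySeries, perturbed: LongevitySeries
) -> np.ndarray:
    """Per-date relative error (L_perturbed - L_original) / L_original.

    Dates where the original longevity is zero get NaN: the relative error
    is undefined there and such dates are excluded from the extremes.
    """
    if original.dates != perturbed.dates:
        raise ValidationError("longevity series are not aligned date-for-date")
    orig = original.longevity
    pert = perturbed.longevity
    out = np.full(orig.size, np.nan)
    defined = orig > 0
    out[defined] = (pert[defined] - orig[defined]) / orig[defined]
    return out


def sensitivity_report(
    census: CensusSeries,
    specs: Sequence[MiscountSpec],
    params: Optional[ColonyParams] = None,
    round_counts: bool = False,
    negative_policy: str = "error",
    initial_brood: str = "integral",
) -> SensitivityReport:
    """Run every miscount case against the unperturbed baseline.

    Each case perturbs the census, recomputes the longevity series, and
    records per-date relative errors plus the signed extremes (largest
    positive, most negative).  A case whose perturbed census becomes
    unsolvable is marked failed without aborting the others.
    """
    if params is None:
        params = ColonyParams()
    solver_kw = dict(negative_policy=negative_policy, initial_brood=initial_brood)
    original = compute_longevity_series(census, params, **solver_kw)
    cases = []
    for spec in specs:
        perturbed = apply_miscount(census, spec, round_counts=round_counts)
        try:
            series = compute_longevity_series(perturbed, params, **solver_kw)
        except InconsistentCensusError as exc:
            cases.append(
                CaseResult(spec=spec, series=None, rel_errors=None, error=str(exc))
            )
            continue
        rel = relative_errors(original, series)
        defined = rel[np.isfinite(rel)]
        max_pos = float(np.max(defined, initial=0.0)) if defined.size else float("nan")
        max_neg = float(np.min(defined, initial=0.0)) if defined.size else float("nan")
        cases.append(
            CaseResult(
                spec=spec,
                series=series,
                rel_errors=rel,
                max_positive=max_pos,
                max_negative=max_neg,
            )
        )
    return SensitivityReport(original=original, cases=cases)
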