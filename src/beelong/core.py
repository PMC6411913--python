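"""Domain types and time conventions shared by all solvers.

The model works on a continuous time axis measured in days.  Census dates
may be given either as calendar dates (``datetime.date``, ``datetime``, or
ISO-8601 strings) or directly as elapsed-day floats; calendar dates are
mapped to floats relative to an origin (the first census date by default).
No sub-day resolution and no timezone handling are attempted.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ValidationError",
    "InconsistentCensusError",
    "ColonyParams",
    "CensusSeries",
    "CappingRateSeries",
    "LongevitySeries",
    "MiscountSpec",
    "CaseResult",
    "SensitivityReport",
    "elapsed_days",
    "as_day_value",
    "STATUS_OK",
    "STATUS_COLLAPSED",
    "STATUS_NO_SOLUTION",
    "STATUS_INCONSISTENT",
    "RATE_OK",
    "RATE_NEGATIVE_CLAMPED",
]

# Per-date status markers for LongevitySeries.
STATUS_OK = "ok"
STATUS_COLLAPSED = "collapsed"          # adult count is zero -> L = 0 exactly
STATUS_NO_SOLUTION = "no_solution"      # emergence supply exhausted below a(t_k)
STATUS_INCONSISTENT = "inconsistent_input"

# Per-interval flags for CappingRateSeries.
RATE_OK = "ok"
RATE_NEGATIVE_CLAMPED = "negative_clamped"

DateLike = Union[dt.date, dt.datetime, str, float, int]


class ValidationError(ValueError):
    """Raised when an input table or parameter set violates its contract."""


class InconsistentCensusError(RuntimeError):
    """Raised when the capping-rate system has a negative solution.

    A negative inferred capping rate means the adult-bee and capped-brood
    counts cannot both be explained by the model: the census is internally
    inconsistent.  ``intervals`` holds the offending interval indices
    (0 denotes the pre-experiment history band).
    """

    def __init__(self, message: str, intervals: Sequence[int] = ()):
        super().__init__(message)
        self.intervals = tuple(intervals)


def _parse_date(value: DateLike):
    """Normalise one date-like value: calendar dates stay dates, numbers stay floats."""
    if isinstance(value, bool):
        raise ValidationError(f"unparseable date: {value!r}")
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, (int, float, np.integer, np.floating)):
        v = float(value)
        if not np.isfinite(v):
            raise ValidationError(f"non-finite day value: {value!r}")
        return v
    if isinstance(value, str):
        try:
            return dt.date.fromisoformat(value.strip())
        except ValueError:
            try:
                return float(value)
            except ValueError:
                raise ValidationError(f"unparseable date: {value!r}") from None
    raise ValidationError(f"unparseable date: {value!r}")


def as_day_value(value: DateLike, origin: DateLike) -> float:
    """Offset of ``value`` from ``origin`` in whole days (float)."""
    v, o = _parse_date(value), _parse_date(origin)
    if isinstance(v, dt.date) != isinstance(o, dt.date):
        raise ValidationError(
            f"cannot mix calendar dates and day numbers: {value!r} vs origin {origin!r}"
        )
    if isinstance(v, dt.date):
        return float((v - o).days)
    return v - o


def elapsed_days(dates: Sequence[DateLike], origin: DateLike) -> np.ndarray:
    """Map dates to float day offsets from ``origin`` (origin itself maps to 0).

    Offsets preserve ordering; negative offsets are returned as-is when a
    date precedes the origin.
    """
    return np.array([as_day_value(d, origin) for d in dates], dtype=float)


@dataclass(frozen=True)
class ColonyParams:
    """Biological constants of the insect's life cycle.

    Parameters
    ----------
    t_egg : float
        Egg-plus-larva period in days, from oviposition to cell capping
        (9 days for *Apis mellifera*).
    t_pupa : float
        Capped (sealed) brood period in days, from capping to eclosion
        (12 days for *A. mellifera*).
    eclosion_rate : float or sequence of float
        Probability that a newly capped pupa survives to emerge as an
        adult.  A scalar applies to all capping intervals; a vector gives
        one value per interval (index 0 is the pre-experiment history).
        Default 0.9.
    """

    t_egg: float = 9.0
    t_pupa: float = 12.0
    eclosion_rate: Union[float, Sequence[float]] = 0.9

    def __post_init__(self):
        if not (self.t_pupa > 0):
            raise ValidationError(f"t_pupa must be positive, got {self.t_pupa}")
        if self.t_egg < 0:
            raise ValidationError(f"t_egg must be nonnegative, got {self.t_egg}")
        p = np.atleast_1d(np.asarray(self.eclosion_rate, dtype=float))
        if p.size == 0 or np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValidationError(
                f"eclosion_rate must lie in (0, 1], got {self.eclosion_rate!r}"
            )

    def eclosion_vector(self, n: int) -> np.ndarray:
        """Per-interval eclosion rates as a length-``n`` vector."""
        p = np.atleast_1d(np.asarray(self.eclosion_rate, dtype=float))
        if p.size == 1:
            return np.full(n, p[0])
        if p.size != n:
            raise ValidationError(
                f"eclosion_rate vector has length {p.size}, expected {n}"
            )
        return p.copy()


def _validated_dates(dates: Sequence[DateLike], what: str):
    parsed = [_parse_date(d) for d in dates]
    if len(parsed) == 0:
        raise ValidationError(f"{what} needs at least one date")
    kinds = {isinstance(d, dt.date) for d in parsed}
    if len(kinds) > 1:
        raise ValidationError(f"{what} mixes calendar dates and day numbers")
    offs = elapsed_days(parsed, parsed[0])
    if np.any(np.diff(offs) <= 0):
        bad = int(np.flatnonzero(np.diff(offs) <= 0)[0]) + 1
        raise ValidationError(
            f"{what} dates must be strictly increasing; "
            f"violation at position {bad} ({parsed[bad]!r})"
        )
    return tuple(parsed)


@dataclass(frozen=True)
class CensusSeries:
    """Dated counts of adult bees and capped brood — the model's only measured input.

    ``dates`` must be strictly increasing; counts must be finite and
    nonnegative.  Counts are stored as floats because the solvers are
    continuous; integer realism is a presentation concern.
    """

    dates: Sequence[DateLike]
    adult_counts: Sequence[float]
    brood_counts: Sequence[float]
    colony: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "dates", _validated_dates(self.dates, "census"))
        for name in ("adult_counts", "brood_counts"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size != len(self.dates):
                raise ValidationError(
                    f"{name} must have one value per date "
                    f"({arr.size} values, {len(self.dates)} dates)"
                )
            if np.any(~np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValidationError(f"{name} row {row}: non-finite value")
            if np.any(arr < 0):
                row = int(np.flatnonzero(arr < 0)[0])
                raise ValidationError(
                    f"{name} row {row}: negative count {arr[row]}"
                )
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def n(self) -> int:
        return len(self.dates)

    def times(self, origin: Optional[DateLike] = None) -> np.ndarray:
        """Census dates as elapsed-day floats (origin defaults to the first date)."""
        return elapsed_days(self.dates, self.dates[0] if origin is None else origin)

    def with_counts(self, adult=None, brood=None) -> "CensusSeries":
        """Copy with replaced count vectors (dates and label unchanged)."""
        return CensusSeries(
            dates=self.dates,
            adult_counts=self.adult_counts if adult is None else adult,
            brood_counts=self.brood_counts if brood is None else brood,
            colony=self.colony,
        )


@dataclass(frozen=True)
class CappingRateSeries:
    """Piecewise-constant daily capping rates inferred from brood counts.

    ``rates[0]`` applies to all time before the first census date (the
    pre-experiment history); ``rates[k]`` for k >= 1 applies on the
    half-open interval [t_{k-1}, t_k).  ``flags`` marks intervals whose
    negative solution was clamped to zero.
    """

    breakpoints: Sequence[DateLike]
    rates: Sequence[float]
    flags: Optional[Sequence[str]] = None

    def __post_init__(self):
        object.__setattr__(
            self, "breakpoints", _validated_dates(self.breakpoints, "rate series")
        )
        arr = np.asarray(self.rates, dtype=float)
        if arr.size != len(self.breakpoints):
            raise ValidationError(
                f"expected {len(self.breakpoints)} rates, got {arr.size}"
            )
        if np.any(~np.isfinite(arr)):
            raise ValidationError("rates must be finite")
        arr.flags.writeable = False
        object.__setattr__(self, "rates", arr)
        flags = self.flags
        if flags is None:
            flags = (RATE_OK,) * arr.size
        flags = tuple(flags)
        if len(flags) != arr.size:
            raise ValidationError("one flag per rate required")
        object.__setattr__(self, "flags", flags)

    @property
    def n(self) -> int:
        return len(self.breakpoints)

    def times(self, origin: Optional[DateLike] = None) -> np.ndarray:
        return elapsed_days(
            self.breakpoints, self.breakpoints[0] if origin is None else origin
        )

    @property
    def clamped(self) -> bool:
        return any(f == RATE_NEGATIVE_CLAMPED for f in self.flags)


@dataclass(frozen=True)
class LongevitySeries:
    """Apparent longevity L(t_k) per census date, with per-date status.

    ``status`` is one of ``ok``, ``collapsed`` (adult count was zero, so
    L = 0 by definition), ``no_solution`` (the emergence history cannot
    supply the observed adults) or ``inconsistent_input``.
    """

    dates: Sequence[DateLike]
    longevity: Sequence[float]
    status: Optional[Sequence[str]] = None
    colony: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "dates", _validated_dates(self.dates, "longevity series"))
        arr = np.asarray(self.longevity, dtype=float)
        if arr.size != len(self.dates):
            raise ValidationError("one longevity value per date required")
        arr.flags.writeable = False
        object.__setattr__(self, "longevity", arr)
        status = self.status
        if status is None:
            status = (STATUS_OK,) * arr.size
        status = tuple(status)
        if len(status) != arr.size:
            raise ValidationError("one status per date required")
        for L, s in zip(arr, status):
            if s in (STATUS_OK, STATUS_COLLAPSED) and not (np.isfinite(L) and L >= 0):
                raise ValidationError(f"longevity {L} invalid for status {s!r}")
        object.__setattr__(self, "status", status)

    @property
    def n(self) -> int:
        return len(self.dates)

    def times(self, origin: Optional[DateLike] = None) -> np.ndarray:
        return elapsed_days(self.dates, self.dates[0] if origin is None else origin)


@dataclass(frozen=True)
class MiscountSpec:
    """A multiplicative miscount over a date window, applied to one count kind.

    ``factor`` 1.2 means "+20% overestimation", 0.8 means "-20%"; the window
    is inclusive on both ends.
    """

    target: str
    factor: float
    window_start: DateLike
    window_end: DateLike

    def __post_init__(self):
        if self.target not in ("adult", "brood"):
            raise ValidationError(f"target must be 'adult' or 'brood', got {self.target!r}")
        if not (self.factor > 0):
            raise ValidationError(f"factor must be positive, got {self.factor}")
        ws, we = _parse_date(self.window_start), _parse_date(self.window_end)
        if isinstance(ws, dt.date) != isinstance(we, dt.date):
            raise ValidationError("window endpoints mix calendar dates and day numbers")
        if as_day_value(we, ws) < 0:
            raise ValidationError("window_start must not exceed window_end")
        object.__setattr__(self, "window_start", ws)
        object.__setattr__(self, "window_end", we)

    @property
    def label(self) -> str:
        pct = (self.factor - 1.0) * 100.0
        return f"{self.target}_{pct:+.0f}pct"


@dataclass(frozen=True)
class CaseResult:
    """One perturbation case of a sensitivity report.

    ``rel_errors`` holds (L_case - L_orig)/L_orig per date, with NaN where
    the original longevity is zero (relative error undefined there).
    ``max_positive``/``max_negative`` are the signed extremes over defined
    dates.  ``error`` carries the solver failure message when the perturbed
    census became unsolvable.
    """

    spec: MiscountSpec
    series: Optional[LongevitySeries]
    rel_errors: Optional[np.ndarray]
    max_positive: float = float("nan")
    max_negative: float = float("nan")
    error: Optional[str] = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass(frozen=True)
class SensitivityReport:
    """Original longevity series plus one perturbed series per miscount case."""

    original: LongevitySeries
    cases: Sequence[CaseResult] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "cases", tuple(self.cases))
        for case in self.cases:
            if case.series is not None and case.series.dates != self.original.dates:
                raise ValidationError("case series must align date-for-date with original")

    def to_frame(self):
        """Tabular layout: date, elapsed day, original L, then per-case L and % error."""
        import pandas as pd

        data = {
            "date": list(self.original.dates),
            "elapsed_day": self.original.times(),
            "L_original": self.original.longevity,
        }
        seen: dict[str, int] = {}
        for case in self.cases:
            label = case.spec.label
            seen[label] = seen.get(label, 0) + 1
            if seen[label] > 1:
                label = f"{label}_{seen[label]}"
            if case.failed:
                data[f"L_{label}"] = np.full(self.original.n, np.nan)
                data[f"rel_err_pct_{label}"] = np.full(self.original.n, np.nan)
            else:
                data[f"L_{label}"] = case.series.longevity
                data[f"rel_err_pct_{label}"] = case.rel_errors * 100.0
        return pd.DataFrame(data)
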