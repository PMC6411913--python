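"""CSV input/output and derived series.

Census schema: columns ``date`` (ISO-8601 calendar date, or a plain
number of elapsed days), ``adult_bees``, ``capped_brood``, optional
``colony``.  Output tables default to two-decimal formatting; full float
precision is available via ``precision=None``.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    CappingRateSeries,
    CensusSeries,
    ColonyParams,
    LongevitySeries,
    SensitivityReport,
    ValidationError,
)

__all__ = [
    "read_census_csv",
    "write_census_csv",
    "write_longevity_csv",
    "write_report_csv",
    "laying_rate_series",
]

REQUIRED_COLUMNS = ("date", "adult_bees", "capped_brood")


def read_census_csv(path) -> CensusSeries:
    """Read and validate a census table.

    Errors name the offending row (0-based, counting data rows): missing
    columns, unparseable dates, duplicate or non-increasing dates, and
    negative counts are all rejected rather than silently repaired.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(frame) == 0:
        raise ValidationError(f"{path}: no census rows")

    raw_dates = frame["date"]
    if pd.api.types.is_numeric_dtype(raw_dates):
        dates = [float(v) for v in raw_dates]
    else:
        dates = []
        for i, v in enumerate(raw_dates):
            try:
                dates.append(dt.date.fromisoformat(str(v).strip()))
            except ValueError:
                raise ValidationError(
                    f"{path} row {i}: unparseable date {v!r} (expected ISO-8601)"
                ) from None
    if len(set(dates)) != len(dates):
        seen = set()
        for i, d in enumerate(dates):
            if d in seen:
                raise ValidationError(f"{path} row {i}: duplicate date {d}")
            seen.add(d)

    for col in ("adult_bees", "capped_brood"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValidationError(f"{path} row {row}: non-numeric {col}")
        if (vals < 0).any():
            row = int((vals < 0).idxmax())
            raise ValidationError(
                f"{path} row {row}: negative {col} ({vals.iloc[row]})"
            )

    colony = None
    if "colony" in frame.columns and frame["colony"].notna().any():
        labels = frame["colony"].dropna().unique()
        colony = str(labels[0])
    try:
        return CensusSeries(
            dates=dates,
            adult_counts=frame["adult_bees"].to_numpy(dtype=float),
            brood_counts=frame["capped_brood"].to_numpy(dtype=float),
            colony=colony,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_census_csv(census: CensusSeries, path) -> None:
    frame = pd.DataFrame(
        {
            "date": [str(d) for d in census.dates],
            "adult_bees": census.adult_counts,
            "capped_brood": census.brood_counts,
        }
    )
    if census.colony is not None:
        frame["colony"] = census.colony
    frame.to_csv(path, index=False)


def _fmt(frame: pd.DataFrame, precision: Optional[int]) -> pd.DataFrame:
    if precision is None:
        return frame
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.{precision}f}" if np.isfinite(v) else "")
    return out


def write_longevity_csv(
    series: LongevitySeries, path, precision: Optional[int] = 2
) -> None:
    """Columns: date, elapsed_day, L_days, status.  Collapsed dates print 0.00."""
    frame = pd.DataFrame(
        {
            "date": [str(d) for d in series.dates],
            "elapsed_day": series.times(),
            "L_days": series.longevity,
            "status": list(series.status),
        }
    )
    _fmt(frame, precision).to_csv(path, index=False)


def write_report_csv(
    report: SensitivityReport, path, precision: Optional[int] = 2
) -> None:
    """Sensitivity-report table: original plus per-case L and % error columns."""
    frame = report.to_frame()
    frame["date"] = frame["date"].map(str)
    _fmt(frame, precision).to_csv(path, index=False)


def laying_rate_series(
    rates: CappingRateSeries, params: ColonyParams
) -> CappingRateSeries:
    """Queen laying rates v(t) implied by the capping rates.

    An egg laid at ``t`` is capped at ``t + t_egg``, so
    ``v(t) = u(t + t_egg)``: the same rate values with every interval
    boundary shifted earlier by ``t_egg`` days.
    """
    first = rates.breakpoints[0]
    if isinstance(first, dt.date):
        shifted = [d - dt.timedelta(days=params.t_egg) for d in rates.breakpoints]
    else:
        shifted = [d - params.t_egg for d in rates.breakpoints]
    return CappingRateSeries(breakpoints=shifted, rates=rates.rates, flags=rates.flags)
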