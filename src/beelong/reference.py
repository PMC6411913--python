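"""Published reference values for the 2013/2014-A colony miscount experiment.

The packaged table holds apparent-longevity series reported for colony
2013/2014-A: the original estimate and the four windowed ±20% miscount
cases (adult bees over/under-counted, capped brood over/under-counted,
window 2013-08-24 through 2013-09-27 inclusive).  These serve as fixed
reference output for regression checks of the relative-error analysis;
they are reported values, not something this package computes from raw
counts (the underlying census is distributed separately by the original
experimenters).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import LongevitySeries, MiscountSpec, STATUS_COLLAPSED, STATUS_OK

__all__ = [
    "load_miscount_reference",
    "reference_longevity_series",
    "MISCOUNT_CASE_SPECS",
]

#: The four miscount cases applied in the reference experiment, in report
#: order: adult +20%, adult -20%, brood +20%, brood -20%.
MISCOUNT_CASE_SPECS = (
    MiscountSpec("adult", 1.2, "2013-08-24", "2013-09-27"),
    MiscountSpec("adult", 0.8, "2013-08-24", "2013-09-27"),
    MiscountSpec("brood", 1.2, "2013-08-24", "2013-09-27"),
    MiscountSpec("brood", 0.8, "2013-08-24", "2013-09-27"),
)

_COLUMNS = (
    "L_original",
    "L_adult_plus20",
    "L_adult_minus20",
    "L_brood_plus20",
    "L_brood_minus20",
)


def load_miscount_reference() -> pd.DataFrame:
    """The reference table as a DataFrame (date, elapsed_day, five L columns)."""
    with resources.files("beelong.data").joinpath(
        "miscount_reference_2013_2014A.csv"
    ).open() as fh:
        return pd.read_csv(fh, parse_dates=["date"])


def reference_longevity_series(column: str = "L_original") -> LongevitySeries:
    """One reference column as a :class:`LongevitySeries`.

    ``column`` is one of ``L_original``, ``L_adult_plus20``,
    ``L_adult_minus20``, ``L_brood_plus20``, ``L_brood_minus20``.
    """
    if column not in _COLUMNS:
        raise KeyError(f"unknown reference column {column!r}; choose from {_COLUMNS}")
    frame = load_miscount_reference()
    values = frame[column].to_numpy(dtype=float)
    status = [STATUS_COLLAPSED if v == 0 else STATUS_OK for v in values]
    return LongevitySeries(
        dates=[d.date() for d in frame["date"]],
        longevity=values,
        status=status,
        colony="2013/2014-A",
    )
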