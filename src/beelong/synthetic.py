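"""Forward simulator: census series from known capping-rate and longevity schedules.

Running the model forward — brood counts from the survival-weighted
capping kernel, adult counts from cumulative emergence truncated at a
prescribed longevity — produces census tables that are exactly consistent
with the model class the solvers assume.  This is the test bed for
round-trip parameter recovery, and with multiplicative lognormal noise it
emulates realistic miscounts that scale with colony size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    CappingRateSeries,
    CensusSeries,
    ColonyParams,
    DateLike,
    ValidationError,
    _validated_dates,
)
from .capping import _kernel_matrix
from .longevity import cumulative_emergence

__all__ = ["ScenarioSpec", "simulate_census", "add_count_noise"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified forward scenario.

    ``capping_rates`` has one value per census date: index 0 is the
    constant pre-history rate (all time before the first census), index
    ``k >= 1`` applies on ``[t_{k-1}, t_k)`` — the same layout the solver
    produces.  ``longevity`` prescribes L(t_k) at each census date.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    count noise (0 disables it); ``seed`` makes the noise reproducible.
    """

    dates: Sequence[DateLike]
    capping_rates: Sequence[float]
    longevity: Sequence[float]
    params: ColonyParams = field(default_factory=ColonyParams)
    noise_cv: float = 0.0
    seed: Optional[int] = None
    colony: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "dates", _validated_dates(self.dates, "scenario"))
        rates = np.asarray(self.capping_rates, dtype=float)
        L = np.asarray(self.longevity, dtype=float)
        n = len(self.dates)
        if rates.size != n:
            raise ValidationError(
                f"expected {n} capping rates (pre-history + one per interval), "
                f"got {rates.size}"
            )
        if L.size != n:
            raise ValidationError(f"expected {n} longevity values, got {L.size}")
        if np.any(~np.isfinite(rates)) or np.any(rates < 0):
            raise ValidationError("capping rates must be finite and nonnegative")
        if np.any(~np.isfinite(L)) or np.any(L < 0):
            raise ValidationError("longevity values must be finite and nonnegative")
        if not (self.noise_cv >= 0):
            raise ValidationError(f"noise_cv must be nonnegative, got {self.noise_cv}")
        rates.flags.writeable = False
        L.flags.writeable = False
        object.__setattr__(self, "capping_rates", rates)
        object.__setattr__(self, "longevity", L)

    def rate_series(self) -> CappingRateSeries:
        return CappingRateSeries(breakpoints=self.dates, rates=self.capping_rates)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dates": [str(d) for d in self.dates],
            "capping_rates": [float(r) for r in self.capping_rates],
            "longevity": [float(v) for v in self.longevity],
            "params": {
                "t_egg": self.params.t_egg,
                "t_pupa": self.params.t_pupa,
                "eclosion_rate": (
                    float(self.params.eclosion_rate)
                    if np.isscalar(self.params.eclosion_rate)
                    else [float(p) for p in np.atleast_1d(self.params.eclosion_rate)]
                ),
            },
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "colony": self.colony,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        params = ColonyParams(**data.get("params", {}))
        return cls(
            dates=data["dates"],
            capping_rates=data["capping_rates"],
            longevity=data["longevity"],
            params=params,
            noise_cv=data.get("noise_cv", 0.0),
            seed=data.get("seed"),
            colony=data.get("colony"),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_census(spec: ScenarioSpec) -> CensusSeries:
    """Evaluate the forward model at the scenario's census dates.

    Brood counts come from the survival-weighted capping kernel; adult
    counts from cumulative emergence truncated at the scenario's L(t_k).
    With ``noise_cv == 0`` the output is exactly model-consistent, so the
    solvers recover the scenario's rates and longevities.
    """
    rates = spec.rate_series()
    times = rates.times()
    p_vec = spec.params.eclosion_vector(spec.capping_rates.size)
    kernel = _kernel_matrix(times, p_vec, spec.params.t_pupa)
    brood = kernel @ spec.capping_rates
    adult = np.array(
        [
            cumulative_emergence(spec.dates[k], float(spec.longevity[k]), rates, spec.params)
            for k in range(len(spec.dates))
        ]
    )
    census = CensusSeries(
        dates=spec.dates, adult_counts=adult, brood_counts=brood, colony=spec.colony
    )
    if spec.noise_cv > 0:
        census = add_count_noise(census, spec.noise_cv, spec.seed)
    return census


def add_count_noise(census: CensusSeries, cv: float, seed: Optional[int]) -> CensusSeries:
    """Multiply every count by an independent lognormal factor with median 1.

    The factor's coefficient of variation equals ``cv``; multiplicative
    noise is used because census miscounts scale with colony size.  Each
    count draws from its own substream derived from the root ``seed``, so
    the perturbation of one count never depends on how many others exist.
    """
    if not (cv >= 0):
        raise ValidationError(f"cv must be nonnegative, got {cv}")
    if cv == 0:
        return census.with_counts()
    sigma = math.sqrt(math.log1p(cv * cv))
    n = census.n
    streams = np.random.SeedSequence(seed).spawn(2 * n)
    factors = np.array(
        [np.exp(sigma * np.random.default_rng(s).standard_normal()) for s in streams]
    )
    return census.with_counts(
        adult=census.adult_counts * factors[:n],
        brood=census.brood_counts * factors[n:],
    )
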