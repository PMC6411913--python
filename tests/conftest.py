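import numpy as np
import pytest

from beelong import CensusSeries, ColonyParams, ScenarioSpec, simulate_census


@pytest.fixture
def params():
    return ColonyParams()


def quad_survival_weight(s1, s2, p, t_pupa, step=0.001):
    """Midpoint-Riemann oracle for the in-cell survival-weight integral."""
    n = max(1, int(round((s2 - s1) / step)))
    s = s1 + (np.arange(n) + 0.5) * (s2 - s1) / n
    return float(np.sum(p ** (s / t_pupa)) * (s2 - s1) / n)


def quad_brood(t, times, rates, p_vec, t_pupa, step=0.001):
    """Brute-force quadrature of the capped-brood balance at time t.

    ``rates[0]`` applies for tau < times[0]; ``rates[j]`` on
    [times[j-1], times[j]).
    """
    n = int(round(t_pupa / step))
    s = (np.arange(n) + 0.5) * t_pupa / n
    tau = t - s
    idx = np.searchsorted(times, tau, side="right")
    idx = np.clip(idx, 0, len(times) - 1)
    u = np.asarray(rates)[idx]
    p = np.asarray(p_vec)[idx]
    return float(np.sum(u * p ** (s / t_pupa)) * t_pupa / n)


def random_scenario(rng, n_min=5, n_max=15, with_zero_adults=False):
    """Random forward scenario within realistic census-study conditions:

    5-15 census dates spaced 4-35 days apart, capping rates 10-500
    brood/day, longevities 5-150 days.
    """
    n = int(rng.integers(n_min, n_max + 1))
    gaps = rng.uniform(4, 35, size=n - 1)
    dates = np.concatenate([[0.0], np.cumsum(gaps)])
    rates = rng.uniform(10, 500, size=n)
    L = rng.uniform(5, 150, size=n)
    if with_zero_adults:
        L[int(rng.integers(n))] = 0.0
    return ScenarioSpec(dates=dates, capping_rates=rates, longevity=L)


@pytest.fixture
def steady_census(params):
    """Steady-state census: rate 100/day, L = 20 days, p = 0.9."""
    b = 100 * params.t_pupa * (0.9 - 1) / np.log(0.9)
    dates = [0.0, 6.0, 25.0, 44.0, 50.0]
    return CensusSeries(dates, [1800.0] * 5, [b] * 5)


@pytest.fixture
def seasonal_census():
    """Noiseless census with the 2013/2014-style irregular spacing."""
    dates = [0.0, 11.0, 19.0, 23.0, 33.0, 39.0, 45.0, 52.0, 61.0,
             75.0, 94.0, 110.0, 145.0]
    rng = np.random.default_rng(20130813)
    rates = rng.uniform(50, 400, size=len(dates))
    L = rng.uniform(10, 90, size=len(dates))
    spec = ScenarioSpec(dates=dates, capping_rates=rates, longevity=L)
    return simulate_census(spec), spec
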