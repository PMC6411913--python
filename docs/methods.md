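# Methods

## The model and its assumptions

The colony is treated as a stage-structured population observed through
two aggregate counts: adult bees `a(t)` and capped brood `b(t)`. Four
assumptions make these two counts sufficient to identify both the daily
capping rate and the apparent longevity:

1. **Immediate removal of dead pupae.** A pupa that dies in its sealed
   cell is removed at once, so in-cell attrition accrues continuously:
   a cohort capped at time `τ` still holds the fraction
   `p(τ)^{s/T_pupa}` of its members `s` days later. Integrating over the
   pupal window gives the brood balance
   `b(t) = ∫₀^{T_pupa} u(t−s) p(t−s)^{s/T_pupa} ds`.
2. **Piecewise-constant rates.** The capping rate `u` and eclosion
   probability `p` are constant between consecutive censuses: `ū_k`,
   `p̄_k` on the half-open interval `[t_{k−1}, t_k)`, and `ū_0`, `p̄_0`
   on all time before the first census. The pre-history band is what
   lets winter longevities reach back months before the experiment
   started.
3. **Constant eclosion rate by default.** `p = 0.9` for every interval;
   a per-interval vector is accepted wherever a scalar is.
4. **Disappearance counted as death.** A worker that leaves and never
   returns is indistinguishable from a dead one in census data; the
   "apparent longevity" `L(t)` is defined as the border age at which an
   average worker leaves the population by *any* route, as the upper
   limit of `a(t) = ∫_{T_pupa}^{T_pupa+L(t)} u(t−s) p(t−s) ds`.
   `L(t)` approximates the oldest member's age only in broodless winter,
   when foraging losses are negligible; outputs are therefore labelled
   apparent longevity, never individual lifespan.

## Solvers and numerical choices

**Capping rates.** Evaluating the brood balance at the `N` census dates
gives an `N×N` linear system in `ū_0 … ū_{N−1}`. Each coefficient is the
closed-form kernel weight
`W(s1, s2) = (T_pupa/ln p)(p^{s2/T_pupa} − p^{s1/T_pupa})` over the age
sub-range during which the cohort was capped in the corresponding
interval (`W = s2 − s1` in the limit `p → 1`). Because a census can only
see brood capped in the preceding `T_pupa` days, the matrix is lower
triangular with strictly positive diagonal; Gaussian elimination
specialises to forward substitution and the solution is unique — no
pivoting, no tolerance. An interval of exactly `T_pupa` days follows the
half-open convention: the boundary age contributes to the newer
interval (a measure-zero choice that never changes any integral).

Solved rates with `|ū_k| < 1e-9 × max|ū|` are snapped to zero before the
sign check. A genuinely negative rate means the counts are mutually
inconsistent — there is provably no capping history in the model class
that produces them. The default policy (`error`) raises and names the
offending interval(s), preserving the estimate's role as a
data-consistency test; `clamp_warn` sets the negative rate to zero,
re-solves the subsequent rows with the clamped value, and flags the
interval, for users who want to proceed anyway.

**Initial brood.** Two initialisations of the pre-history band are
offered. The default, `integral`, applies the brood balance literally at
`t_0`, i.e. `ū_0 = b(t_0)/W(0, T_pupa)`: the history is a constant rate
whose survivors are age-weighted like every later cohort. The
alternative, `uniform`, assumes the initial capped brood is spread
uniformly over age, `ū_0 = b(t_0)/T_pupa`. At `p = 0.9` the two differ
by a factor `T_pupa/W(0,T_pupa) ≈ 1.054` in `ū_0` only; the rest of the
system is identical. `integral` is the default because it keeps the
first row in the same model class as every other row, and it is the mode
under which forward-simulated censuses are recovered exactly.

**Longevity inversion.** For fixed rates the cumulative-emergence
function `G(L)` — adults emerged in the `L` days ending at
`t_k − T_pupa` — is continuous, piecewise linear and nondecreasing, with
breakpoints at the capping-interval boundaries. The smallest root of
`G(L) = a(t_k)` is found exactly by walking the intervals backward in
time and interpolating inside the interval where the accumulated
emergence first reaches `a(t_k)`; no iteration, tolerance or bracketing
is involved, and the result satisfies `G(L*) = a(t_k)` to floating-point
precision. Deterministic edge cases: `a = 0` returns `L = 0` with status
`collapsed`; a root falling on a zero-rate plateau returns the smallest
`L` on the plateau; a hard cap (default 10⁴ days) guards the only
unbounded case — `ū_0 = 0`, where `G` saturates below `a` — returning
status `no_solution`. Negative input rates yield status
`inconsistent_input` rather than a number.

## Tunable parameters

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| `t_egg` | 9 | days | Oviposition → capping; only shifts laying-rate dates |
| `t_pupa` | 12 | days | Capping → eclosion; sets the kernel window |
| `eclosion_rate` | 0.9 | — | Pupal survival probability, scalar or per interval |
| `initial_brood` | `integral` | — | Pre-history anchoring (see above) |
| `negative_policy` | `error` | — | Inconsistent-census handling |
| longevity cap | 10⁴ | days | Search bound for the zero-history pathology |

All three biological constants are plain flags, so the estimator applies
to any social insect whose life cycle (`T_egg`, `T_pupa`, `p`) is known
and whose imagos and pupae can be counted at intervals.

## The synthetic generator

`ScenarioSpec` fixes census dates, a capping-rate profile on the census
grid plus one pre-history value, a longevity schedule, and the colony
constants; `simulate_census` evaluates both balances forward, exactly.
Default study conditions mirror the field design the estimator targets:
irregular censuses 4–35 days apart, 5–15 dates per series, capping rates
10–500 brood/day, longevities 5–150 days — counts then land in the
10²–10⁴ range typical of a single hive. Noise is multiplicative
lognormal with median 1 and a chosen coefficient of variation, because
census miscounts scale with colony size; each count draws from its own
substream spawned from one root seed, so a count's perturbation does not
depend on how many counts exist.

What the generator does *not* emulate — and hence what passing
round-trip tests do and do not show: real capping rates vary
continuously within intervals, eclosion success varies with season and
colony state, counts are integers, and real miscounts can be correlated
across dates. Exact recovery on noiseless scenarios demonstrates that
the inversion is the exact inverse of the forward model on its own model
class, not that field estimates are unbiased; the windowed-miscount and
lognormal-noise analyses probe robustness, not realism.

## Sensitivity analysis

A miscount case multiplies one count kind by a factor over a date window
(both endpoints inclusive); perturbed counts stay real-valued unless
integer rounding is requested, since the model is continuous. Relative
errors `(L_case − L_orig)/L_orig` are undefined where `L_orig = 0` and
such dates are excluded from the reported extremes (largest positive and
most negative are reported separately). Two structural facts follow from
the model, and are verified rather than hard-coded: adult-count errors
change `L` only at census dates inside the window (the adult count
enters only its own date's inversion), while brood-count errors distort
the inferred rates and therefore keep distorting `L` after the window
closes. A subtlety reproduced by the triangular structure: a brood
miscount at the *first* census date inside a window can leave that
date's own `L` unchanged, because `b(t_0)` only anchors the pre-history
rate that later dates draw on.

## Known limitations

* Rates are deconvolved without smoothing or regularisation; noisy brood
  counts produce noisy, occasionally negative rates by design (that
  signal is the consistency check).
* `p(t)` is not estimated from data; it must be supplied.
* The discrete census cannot resolve rate changes within an interval;
  two censuses closer than `T_pupa` days share brood cohorts and the
  system row spans several intervals accordingly.
* Calendar dates are handled at day resolution only; fractional `t_egg`
  shifts of calendar breakpoints are truncated to whole days (float
  time axes keep full precision).
* The packaged 2013/2014-A reference table contains reported longevity
  values only; reproducing them from raw counts requires the original
  census, supplied by the user as `data/census_2013_2014A.csv`.
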