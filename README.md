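# beelong

Estimate the seasonal **apparent longevity** of a honeybee colony from
nothing but dated census totals of adult bees and capped brood.

Beekeepers and field ecologists can photograph every comb and the hive
interior just after dawn and count two quantities accurately: the number of
adult bees `a(t)` and the total capped (sealed) brood `b(t)`. Individual
marking and follow-up of thousands of workers is impractical, so the
*lifespan* of workers in the field is hard to measure directly. `beelong`
inverts a simple stage-structured population model to obtain, at every
census date, the *apparent longevity* `L(t)` — the border age at which an
average worker disappears from the colony, lumping together death,
predation, pesticide loss and bees that simply fail to return. Because
the inversion fails on mutually inconsistent counts, `L(t)` doubles as a
consistency check on field data.

## Model

Let `u(t)` be the number of brood newly capped per day, `p(t)` the
eclosion probability of a pupa capped at `t` (default 0.9), and
`T_pupa = 12` days the capped-brood period. Assuming a dead pupa is
removed from its cell immediately, the standing capped brood is

    b(t) = ∫₀^{T_pupa} u(t − s) · p(t − s)^{s/T_pupa} ds

and the adult population consists of the cohorts that have emerged but
not yet reached the disappearance age `L(t)`:

    a(t) = ∫_{T_pupa}^{T_pupa + L(t)} u(t − s) · p(t − s) ds

With `u` and `p` constant between consecutive censuses (`ū_k` on
`[t_{k−1}, t_k)`, `ū_0` before the first census), the brood equation
evaluated at the census dates becomes a lower-triangular linear system
whose unique solution is the capping-rate profile; the adult equation is
then solved for `L(t_k)` exactly by walking the capping intervals
backward in time and interpolating (the cumulative-emergence function is
piecewise linear and nondecreasing). The queen's laying rate follows as
`v(t) = u(t + T_egg)` with `T_egg = 9` days. All three constants are
configurable, so the method applies to any social insect with a known
life cycle.

The package also ships:

* a **forward simulator** (`ScenarioSpec` → `simulate_census`) that
  generates census tables from known capping-rate and longevity
  schedules, with optional multiplicative lognormal count noise — the
  test bed for round-trip parameter recovery;
* a **miscount-sensitivity analysis** (`sensitivity_report`) that
  multiplies adult or brood counts by a factor over a date window and
  reports per-date relative errors of `L(t)`, reproducing the
  characteristic structure that adult-count errors are *local* to the
  miscounted window while brood-count errors *persist* beyond it;
* packaged **reference longevity series** for colony 2013/2014-A under
  four ±20% miscount cases, used as fixed regression values.

## Worked example

`demo.csv`:

```csv
date,adult_bees,capped_brood
2013-08-13,11000,4800
2013-08-24,12500,5200
2013-09-27,9000,3100
2013-10-13,8000,900
```

```sh
beelong estimate demo.csv -o L.csv --rates-out rates.csv
```

`L.csv`:

```csv
date,elapsed_day,L_days,status
2013-08-13,0.00,29.00,ok
2013-08-24,11.00,32.96,ok
2013-09-27,45.00,30.73,ok
2013-10-13,61.00,35.50,ok
```

Reading: on 13 August the 11 000 adults are explained by the bees that
emerged during the preceding 29.0 days, so a typical worker disappears at
age 29 days (12 days as a capped pupa plus 29 days as an adult). The
solved capping rates in `rates.csv` drop from ≈421 brood/day before the
experiment to ≈79/day by mid-October (brood rearing winding down toward
winter), and each rate is dated back 9 days to the laying interval that
produced it. A `status` other than `ok` marks a collapsed colony
(`a = 0`), an exhausted emergence history, or inconsistent counts.

The same pipeline is available as a library:

```python
import beelong as bl

census = bl.read_census_csv("demo.csv")
series = bl.compute_longevity_series(census, bl.ColonyParams())
```

Other subcommands: `beelong perturb` (windowed miscount), `beelong
simulate` (forward scenario YAML → census CSV), `beelong report`
(multi-case sensitivity table). Exit codes: 0 success, 2 validation
error, 3 inconsistent census.

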