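# Methods

This note documents the model implemented by `t1dburden`, its assumptions,
parameter defaults, numerical choices, and what the synthetic data can and
cannot show.

## The estimation chain

The pipeline estimates national, regional and global counts of incident and
prevalent type 1 diabetes cases from three country-level inputs: childhood
(0–14 y) incidence per 100,000 person-years, population by age band, and the
under-5 child mortality rate CM (per 1000 live births). Age is resolved into
four bands — 0–14, 15–39, 40–64, 65+ — a compromise between age detail and
the resolution of available epidemiological data. Stages:

1. countries without an observed childhood rate receive a donor country's
   rate (donor chosen by expert judgement, supplied as a map; donors must
   themselves be observed — chains are refused because no chaining rule is
   defined);
2. adult band rates = childhood rate × scaling ratios;
3. incident cases = rate × population / 10⁵ per band, kept as real numbers
   (rounding happens only in report emission);
4. penalty `Pen = CM / 130`, mean duration
   `D(g) = max(D_max(g) · (1 − Pen), D_min)`;
5. steady-state prevalence by onset band `P(g) = I(g) · D(g)`;
6. allocation of `P(g)` to attained-age bands by expected person-years;
7. aggregation and crude / age-standardised prevalence per 1000.

## Assumptions

* **Epidemiological steady state.** `P = I × D` assumes annual new cases
  equal annual deaths among cases. Rising incidence or improving survival
  violate this; estimates are therefore equilibrium approximations, not
  projections.
* **Band-constant rates.** Incidence is flat within a band; the four-band
  resolution is the model's resolution.
* **A single scalar health-system proxy.** All between-country variation in
  survival with type 1 diabetes is carried by CM through the penalty. CM is
  chosen over full life expectancy because it is largely insensitive to
  HIV/AIDS mortality. The constant 130 sits just above the highest national
  CM in the reference era, so `Pen ∈ [0, 1)` for era-consistent inputs;
  larger CM values clamp to 1 with a logged warning rather than erroring.
* **One world survival schedule.** Attained-age allocation uses a single
  cumulative-survival schedule applied to every country (as the original
  spreadsheet analysis did with its Danish-derived schedule), not
  per-country survival curves.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| scaling ratios (core) | 1.00 / 0.50 / 0.30 / 0.25 | — | Danish registry ratios of adult to childhood incidence |
| scaling ratios (china preset) | 1.00 / 0.57 / 0.28 / 0.19 | — | large Chinese population study; sensitivity use |
| `D_max` per onset band | 60.4 / 43.4 / 21.1 / 8.5 | years | remaining life expectancy from onset under optimal (Danish-level) care |
| `D_min` | 0.5 | years | assumed survival where insulin access is severely limited |
| penalty constant | 130 | per 1000 | just above the highest national under-5 mortality in the reference era |
| cap age | 99 | years | finite end for the open 65+ band's person-year arithmetic; configurable |
| mean onset ages | 7.5 / 27 / 52 / 72 | years | within-band onset placement; affects only within-band person-year overlap, never totals |

**Duration floor.** The 0.5-year global minimum is implemented as a hard
floor on the formula's output, `max(D_max(1−Pen), 0.5)`. This reproduces
both stated behaviours at the extremes (full duration at Pen = 0, 0.5 y as
Pen → 1) without needing a list of countries to which the minimum was
assigned directly; any such bespoke per-country overrides cannot be
reproduced here.

## Survival schedules and attained-age allocation

A schedule stores, per onset band g, the mean onset age `a_g` and cumulative
survival `S` at a sorted set of knot ages (the ends of the closed bands at
minimum; extra knots, e.g. 5-year steps inside the open 65+ band or a value
at the cap age, refine the curve). Between knots `S` is linear — the minimal
assumption given end-of-band values; if the last knot is below the cap age,
`S` falls linearly to 0 at the cap, and a knot at the cap age truncates
there (all survivors die at the cap).

Expected person-years per incident case in attained band b are trapezoidal
integrals of this piecewise-linear curve over the band (starting at `a_g`,
where S ≡ 1, within the onset band). Weights are person-years normalised to
sum exactly to 1, so allocation conserves totals to float precision.

**Penalty in allocation.** The penalty enters only through the durations in
`P = I × D`; allocation weights come from the penalty-free schedule, i.e.
person-years are rescaled proportionally and band shares are
penalty-invariant. This is deterministic, conserves mass trivially, and
matches the steady-state identity exactly. For users who read shortened
survival as curtailing old age, `tail_truncate` removes person-years from
the oldest attained bands first instead; both modes keep row sums at 1.

**Synthetic schedule generation.** Per onset band, survival in time since
onset is Weibull with a seed-drawn shape in [1.2, 2.2]; the scale is solved
(Brent's method on the trapezoidal expectancy, xtol 1e-8) so the implied
penalty-free expectancy equals the band's `D_max`. Targets above
`cap − a_g` are infeasible and raise; a target exactly at the bound yields
step survival (everyone survives to the cap). Extra knots inside the 65+
band are required here: with band-end knots only, a linear tail to zero at
the cap cannot represent any expectancy below `(cap − a_g)/2`, which would
make the 8.5-year target for onset at 65+ unreachable.

## The cohort-simulation oracle

`simulate_steady_state` validates the analytic identity independently:
every simulated year injects each band's annual incident cases at its mean
onset age, ages all cohorts in one-year steps, and kills according to the
schedule's survival curve with time since onset rescaled so that life
expectancy matches the supplied durations (`S'(t) = S(t·E/D)`). A mid-year
census after ≥ cap-age years counts the living by attained band. Observed
agreement with the analytic totals is well within 2% across seeds; the
band-level distribution additionally matches the analytic weights when
durations equal the schedule expectancies, up to the ~half-year band-edge
blur inherent to one-year census steps.

Note the time-rescaled simulation shifts its age distribution when the
penalty shortens durations, whereas the default allocation keeps band
shares penalty-invariant by design; oracle equivalence under penalty is
therefore asserted on totals, where both constructions agree.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the real inputs: ~200
countries; log-normal childhood incidence (log-mean 1.4, log-sd 1.2 on the
per-100k scale → median ≈ 4, central 98% ≈ 0.25–66, spanning the two orders
of magnitude seen across real registries); CM uniform within income-group
intervals HIC (2, 10), UMIC (5, 25), LMIC (15, 70), LIC (40, 125), all
inside [0, 130); heavy-tailed country populations normalised to a 7.5
billion world; child population share rising with CM; income mix
0.30/0.27/0.25/0.18 and region mix 0.27/0.24/0.22/0.165/0.025/0.08
(approximate real country counts); and half the countries without observed
incidence (registry data existed for roughly half the world's countries),
each mapped to a same-region observed donor. Missing-incidence selection is
stratified within region and capped at `n_region − 1` so a donor always
exists; labels are redrawn (rarely) until every group and region is
represented, so aggregate reports always have their full row set.

It does **not** emulate the real joint distribution of incidence with
geography (e.g. the Northern-European cluster), real country sizes, or any
actual 2017 value. Passing tests therefore demonstrate the correctness and
invariances of the *method* — conservation, monotonicity in CM, scenario
algebra, oracle equivalence — not agreement with published country numbers,
which would require the original input tables.

## Age standardisation

The WHO world standard population 2000–2025 is shipped as a constant. The
published 18 five-year proportions (8.86, 8.69, 8.60, 8.47, 8.22, 7.93,
7.61, 7.15, 6.59, 6.04, 5.37, 4.55, 3.72, 2.96, 2.21, 1.52, 0.91, 0.63 per
cent) sum to 100.03 — a known rounding artifact — and aggregate to the four
bands as 26.15 / 39.38 / 26.27 / 8.23, which are normalised by 100.03 to
weights 0.26142 / 0.39368 / 0.26262 / 0.08228 (sum exactly 1). The
standardised rate is the weight-dot-product of band prevalence rates per
1000. The crude-prevalence denominator is the population of the countries
included in the run; no allowance is made for countries absent from the
input table.

## Reporting conventions

Counts are emitted in thousands at 2 decimals, rounded half away from zero
(the spreadsheet convention); totals are rounded from unrounded sums, so a
printed row's band cells can disagree with its printed total by up to 0.01
thousand per rounded cell. Shares are reported unrounded (summing to
exactly 100 across a partition) and integer-rounded.

## Sensitivity scenarios

A scenario is a named set of overrides re-run against otherwise identical
inputs: `override_penalty` (e.g. 0 to disable the penalty),
`duration_scale` (multiplier on all `D_max`), or `ratio_set`. Duration-only
scenarios provably leave incident counts bit-identical. The shipped
`reduced mean duration` multiplier (0.72) and `changed incidence scaling 1`
ratios (1.00/0.35/0.20/0.15) are editable placeholders — the originally
used values are not published in accessible form — while
`changed incidence scaling 2` (all adult bands at 0.5) is as published.

## Problem sizes

Default runs use 200 synthetic countries, 1000 random draws for the
conservation check, five seeds for oracle equivalence, and a one-year-step
simulation over a 100-year horizon; the whole suite and the acceptance
script each run in seconds.

## Known limitations

* Steady-state assumption: no trends in incidence or survival.
* One scalar (CM) proxies the entire health-system effect on survival.
* The shared survival schedule ignores between-country differences in the
  *shape* (not just the level) of survival.
* No sex or urban/rural stratification (insufficient input data, by
  design); no uncertainty intervals — sensitivity is scenario-based.
* Published headline country estimates cannot be reproduced without the
  original country input tables; all validation here is structural or on
  synthetic data, plus internal-consistency checks of the published
  summary table's printed cells.
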