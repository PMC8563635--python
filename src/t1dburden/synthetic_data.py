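"""Seeded synthetic country tables and survival schedules.

Real inputs to the burden model are a ~200-row country table (registry
childhood incidence, UN demography, under-5 mortality) and a shared
cumulative-survival schedule derived from Danish data. Neither is
redistributable here, so this module generates tables with the same
statistical structure:

* childhood incidence is log-normal across countries — the real
  distribution is heavily right-skewed, from under 1 per 100,000
  person-years in East Asia to around 60 in Finland;
* under-5 mortality (CM) is drawn uniformly within an income-group
  interval, low for HICs and high for LICs, all inside [0, 130) — the
  penalty mechanism is only interesting because CM covaries with income;
* population age structure skews young where CM is high;
* a configurable fraction of countries is emitted without observed
  incidence, paired with a same-region observed donor, mirroring how the
  real analysis extrapolated rates to countries without registry studies.

The survival-schedule generator picks a Weibull survival curve per onset
band and calibrates its scale so the schedule's implied penalty-free
remaining life expectancy hits the configured band maximum.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.optimize import brentq

from .bands import BANDS, DEFAULT_CAP_AGE, N_BANDS
from .country_data import (
    INCOME_GROUPS,
    REGIONS,
    CountryRecord,
    CountryTable,
)
from .duration_model import DurationParams
from .errors import CalibrationError, GenerationError
from .prevalence_model import (
    DEFAULT_MEAN_ONSET_AGES,
    SurvivalSchedule,
    implied_expectancy,
)

_DEFAULT_CM_RANGES: dict[str, tuple[float, float]] = {
    "HIC": (2.0, 10.0),
    "UMIC": (5.0, 25.0),
    "LMIC": (15.0, 70.0),
    "LIC": (40.0, 125.0),
}

_DEFAULT_INCOME_MIX: dict[str, float] = {
    "HIC": 0.30,
    "UMIC": 0.27,
    "LMIC": 0.25,
    "LIC": 0.18,
}

_DEFAULT_REGION_MIX: dict[str, float] = {
    "Africa": 0.27,
    "Asia": 0.24,
    "Europe": 0.22,
    "LAC": 0.165,
    "NA": 0.025,
    "Oceania": 0.08,
}


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic world.

    Defaults emulate the structure of the real 2017 inputs: ~200 countries,
    incidence spanning roughly two orders of magnitude, CM between ~2 and
    <130 per 1000, and about half of countries lacking an observed rate.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_countries: int = 200
    incidence_log_mean: float = 1.4  # log of per-100k rate; median ≈ 4
    incidence_log_sd: float = 1.2
    cm_range_by_income: dict[str, tuple[float, float]] = _DEFAULT_CM_RANGES
    population_scale: float = 7.5e9  # world total, persons
    income_mix: dict[str, float] = _DEFAULT_INCOME_MIX
    region_mix: dict[str, float] = _DEFAULT_REGION_MIX
    frac_missing_incidence: float = 0.5

    @field_validator("n_countries")
    @classmethod
    def _n_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"n_countries must be >= 1, got {v}")
        return v

    @field_validator("frac_missing_incidence")
    @classmethod
    def _frac_in_unit(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"frac_missing_incidence must lie in [0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _mixes_and_ranges(self) -> "SyntheticConfig":
        for name, mix, keys in (
            ("income_mix", self.income_mix, INCOME_GROUPS),
            ("region_mix", self.region_mix, REGIONS),
        ):
            if set(mix) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} proportions must be >= 0")
            if not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1, got {sum(mix.values())}")
        if set(self.cm_range_by_income) != set(INCOME_GROUPS):
            raise ValueError(f"cm_range_by_income must have keys {INCOME_GROUPS}")
        for grp, (lo, hi) in self.cm_range_by_income.items():
            if not (0.0 <= lo <= hi < 130.0):
                raise ValueError(
                    f"cm range for {grp} must lie within [0, 130), got ({lo}, {hi})"
                )
        return self


def _synthetic_iso3(i: int) -> str:
    """Deterministic pseudo-ISO3 codes: XAA, XAB, ... (X prefix avoids real codes)."""
    hi, lo = divmod(i, 26)
    return "X" + chr(ord("A") + hi) + chr(ord("A") + lo)


def _age_structure(rng: np.random.Generator, cm: float) -> np.ndarray:
    """Band population shares; the child share grows with CM (young population)."""
    child = 0.15 + 0.28 * (cm / 130.0) + rng.normal(0.0, 0.015)
    child = float(np.clip(child, 0.10, 0.50))
    # adult split ages with development: interpolate young ↔ old structure
    t = cm / 130.0
    adult = (1 - t) * np.array([0.40, 0.36, 0.24]) + t * np.array([0.55, 0.33, 0.12])
    adult = adult + rng.normal(0.0, 0.01, 3)
    adult = np.clip(adult, 0.01, None)
    adult = adult / adult.sum() * (1.0 - child)
    return np.concatenate(([child], adult))


def generate_country_table(
    config: SyntheticConfig,
) -> tuple[CountryTable, dict[str, str]]:
    """Generate a seeded synthetic CountryTable plus its donor map.

    Deterministic for a fixed config. Countries flagged as lacking observed
    incidence are chosen per region (capped so each region keeps at least
    one observed country) and mapped to a same-region observed donor.
    """
    if config.n_countries > 26 * 26:
        raise GenerationError(f"at most {26 * 26} synthetic countries supported")
    rng = np.random.default_rng(config.seed)
    n = config.n_countries

    # redraw (rarely) until every group and region is represented, so the
    # aggregate report always has its full set of rows
    incomes = regions = None
    for _ in range(1000):
        incomes = rng.choice(
            list(config.income_mix), size=n, p=list(config.income_mix.values())
        )
        regions = rng.choice(
            list(config.region_mix), size=n, p=list(config.region_mix.values())
        )
        need_income = {g for g, p in config.income_mix.items() if p > 0}
        need_region = {r for r, p in config.region_mix.items() if p > 0}
        income_ok = n < len(need_income) or need_income <= set(incomes)
        region_ok = n < len(need_region) or need_region <= set(regions)
        if income_ok and region_ok:
            break
    else:
        raise GenerationError("could not cover all income groups and regions")
    incidence = rng.lognormal(config.incidence_log_mean, config.incidence_log_sd, n)
    cm = np.array(
        [rng.uniform(*config.cm_range_by_income[g]) for g in incomes]
    )
    # heavy-tailed country sizes, normalised to the world total
    raw_pop = rng.lognormal(0.0, 1.5, n)
    totals = raw_pop / raw_pop.sum() * config.population_scale
    shares = np.vstack([_age_structure(rng, c) for c in cm])
    populations = shares * totals[:, None]

    # choose missing-incidence countries per region; keep >=1 observed per region
    missing = np.zeros(n, dtype=bool)
    donor_map: dict[str, str] = {}
    iso3 = [_synthetic_iso3(i) for i in range(n)]
    for reg in REGIONS:
        idx = np.nonzero(regions == reg)[0]
        if idx.size == 0:
            continue
        k = min(int(np.floor(config.frac_missing_incidence * idx.size)), idx.size - 1)
        if k <= 0:
            continue
        chosen = rng.choice(idx, size=k, replace=False)
        missing[chosen] = True
        observed_in_region = [i for i in idx if not missing[i]]
        if not observed_in_region:
            raise GenerationError(
                f"region {reg} needs donors but has no observed country"
            )
        for i in chosen:
            donor_map[iso3[i]] = iso3[int(rng.choice(observed_in_region))]

    records = []
    for i in range(n):
        records.append(
            CountryRecord(
                iso3=iso3[i],
                name=f"Synthetic Country {i:03d}",
                income_group=str(incomes[i]),
                region=str(regions[i]),
                population=tuple(float(p) for p in populations[i]),
                childhood_incidence=None if missing[i] else float(incidence[i]),
                incidence_source="missing" if missing[i] else "observed",
                cm=float(cm[i]),
            )
        )
    table = CountryTable(
        records=tuple(records),
        provenance=f"synthetic (seed={config.seed}, n={n})",
    )
    return table, donor_map


# -- survival schedule ------------------------------------------------------

_TAIL_KNOT_STEP = 5.0  # years between extra knots inside the open 65+ band


def _knot_ages(g: int, onset_age: float, cap_age: float) -> list[float]:
    """Band-end knots after onset plus 5-year refinement inside the open band."""
    ages = [b.end for b in BANDS[g:] if b.end is not None and b.end > onset_age]
    start = max(BANDS[-1].start, onset_age)
    a = math.floor(start / _TAIL_KNOT_STEP) * _TAIL_KNOT_STEP + _TAIL_KNOT_STEP
    while a < cap_age:
        ages.append(a)
        a += _TAIL_KNOT_STEP
    return sorted(set(ages))


def generate_survival_schedule(
    seed: int,
    duration_params: DurationParams | None = None,
    cap_age: float = DEFAULT_CAP_AGE,
    mean_onset_ages: tuple[float, ...] = DEFAULT_MEAN_ONSET_AGES,
) -> SurvivalSchedule:
    """Calibrated synthetic stand-in for the (unavailable) Danish schedule.

    Per onset band, survival in time since onset is Weibull with a
    seed-drawn shape in [1.2, 2.2]; the scale is solved so the schedule's
    implied penalty-free expectancy (trapezoidal person-years, linear tail
    to zero at cap) equals the band's configured global maximum mean
    duration. Targets above cap_age − onset age are infeasible; a target
    exactly at that bound yields step survival (everyone survives to cap).
    """
    params = duration_params or DurationParams()
    rng = np.random.default_rng(seed)
    shapes = rng.uniform(1.2, 2.2, N_BANDS)

    knots_all: list[tuple[tuple[float, float], ...]] = []
    for g in range(N_BANDS):
        a = mean_onset_ages[g]
        target = params.max_duration[g]
        bound = cap_age - a
        if target > bound + 1e-9:
            raise CalibrationError(
                f"onset band {BANDS[g].label}: target expectancy {target} exceeds "
                f"cap_age − onset age = {bound}"
            )
        ages = _knot_ages(g, a, cap_age)
        if math.isclose(target, bound, rel_tol=0, abs_tol=1e-9):
            # boundary: step survival, everyone survives to the cap
            knots_all.append(tuple((age, 1.0) for age in ages + [cap_age]))
            continue

        k = shapes[g]

        def expectancy_for(scale: float) -> float:
            s_vals = np.exp(-(((np.asarray(ages) - a) / scale) ** k))
            sched = _single_band_schedule(g, a, ages, s_vals, cap_age)
            return implied_expectancy(g, sched)

        lo, hi = 1e-2, 1e4
        try:
            scale = brentq(lambda x: expectancy_for(x) - target, lo, hi, xtol=1e-8)
        except ValueError as exc:
            raise CalibrationError(
                f"onset band {BANDS[g].label}: cannot reach expectancy {target} "
                f"with the knot layout (feasible up to {expectancy_for(hi):.2f})"
            ) from exc
        s_vals = np.exp(-(((np.asarray(ages) - a) / scale) ** k))
        knots_all.append(tuple((float(x), float(s)) for x, s in zip(ages, s_vals)))

    return SurvivalSchedule(
        mean_onset_age=tuple(mean_onset_ages),
        knots=tuple(knots_all),
        cap_age=cap_age,
    )


def _single_band_schedule(
    g: int, onset_age: float, ages: list[float], s_vals: np.ndarray, cap_age: float
) -> SurvivalSchedule:
    """Scratch schedule carrying one band's candidate knots (for calibration)."""
    onset = list(DEFAULT_MEAN_ONSET_AGES)
    onset[g] = onset_age
    knots: list[tuple[tuple[float, float], ...]] = [()] * N_BANDS
    knots[g] = tuple((float(x), float(s)) for x, s in zip(ages, s_vals))
    return SurvivalSchedule(
        mean_onset_age=tuple(onset), knots=tuple(knots), cap_age=cap_age
    )
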