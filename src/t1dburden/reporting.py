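"""Aggregation, crude and age-standardised prevalence, and table emitters.

Country estimates are summed into income-group, region and world
aggregates. Prevalence proportions are reported crude (1000 × cases /
population) and age-standardised to the WHO world standard population for
2000–2025, whose published 5-year proportions are aggregated here into the
model's four bands (the published 18 values sum to 100.03 owing to
rounding; the four-band weights are renormalised to sum to 1 — the
arithmetic is laid out in the methods note).

Rounding follows the spreadsheet convention (half away from zero) and
happens only at emission: totals are computed from unrounded sums, so a
printed row's band cells may disagree with its printed total by up to 0.01
thousand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BAND_LABELS, N_BANDS
from .country_data import INCOME_GROUPS, REGIONS
from .errors import StructuralError, ValidationError

#: WHO world standard population 2000–2025, percent by 5-year group.
WHO_STANDARD_5YR: dict[str, float] = {
    "0-4": 8.86,
    "5-9": 8.69,
    "10-14": 8.60,
    "15-19": 8.47,
    "20-24": 8.22,
    "25-29": 7.93,
    "30-34": 7.61,
    "35-39": 7.15,
    "40-44": 6.59,
    "45-49": 6.04,
    "50-54": 5.37,
    "55-59": 4.55,
    "60-64": 3.72,
    "65-69": 2.96,
    "70-74": 2.21,
    "75-79": 1.52,
    "80-84": 0.91,
    "85+": 0.63,
}

_FIVE_YEAR_TO_BAND = {
    "0-14": ("0-4", "5-9", "10-14"),
    "15-39": ("15-19", "20-24", "25-29", "30-34", "35-39"),
    "40-64": ("40-44", "45-49", "50-54", "55-59", "60-64"),
    "65+": ("65-69", "70-74", "75-79", "80-84", "85+"),
}


@dataclass(frozen=True)
class StandardPopulation:
    """Band weights of a standard population; must sum to 1."""

    weights: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.weights) != N_BANDS:
            raise StructuralError(f"need {N_BANDS} weights, got {len(self.weights)}")
        if any(w < 0 for w in self.weights):
            raise ValueError(f"weights must be >= 0, got {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _who_four_band_weights() -> tuple[float, ...]:
    total = sum(WHO_STANDARD_5YR.values())
    return tuple(
        sum(WHO_STANDARD_5YR[k] for k in groups) / total
        for groups in _FIVE_YEAR_TO_BAND.values()
    )


WHO_WORLD_STANDARD = StandardPopulation(
    weights=_who_four_band_weights(), name="WHO world standard 2000-2025"
)


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (spreadsheet convention), element-wise."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


# -- estimate container -----------------------------------------------------

_MEASURE_PREFIXES = ("inc", "prevo", "preva")
_BAND_KEYS = ("0_14", "15_39", "40_64", "65p")
POP_KEYS = tuple(f"pop_{k}" for k in _BAND_KEYS)

COUNTRY_COLUMNS = (
    ["iso3", "income_group", "region"]
    + [f"pop_{k}" for k in _BAND_KEYS]
    + [f"inc_{k}" for k in _BAND_KEYS]
    + [f"prevo_{k}" for k in _BAND_KEYS]
    + [f"preva_{k}" for k in _BAND_KEYS]
)

GROUP_ORDER = ("World",) + INCOME_GROUPS + REGIONS


def _numeric_columns() -> list[str]:
    return [c for c in COUNTRY_COLUMNS if c not in ("iso3", "income_group", "region")]


@dataclass(frozen=True)
class EstimateTable:
    """Per-country incident/prevalent estimates plus group aggregates.

    ``countries`` has one row per country (populations; incident cases per
    onset band ``inc_*``; prevalent cases per onset band ``prevo_*`` and per
    attained band ``preva_*``). ``aggregates`` is indexed by World, the four
    income groups and the six regions, and is recomputed — never stored —
    so each aggregate is the exact sum of its members by construction.
    """

    countries: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COUNTRY_COLUMNS if c not in self.countries.columns]
        if missing:
            raise StructuralError(f"country frame missing columns: {missing}")

    @property
    def aggregates(self) -> pd.DataFrame:
        frames = [
            self.slice("world"),
            self.slice("income_group"),
            self.slice("region"),
        ]
        agg = pd.concat(frames)
        return agg.reindex([g for g in GROUP_ORDER if g in agg.index])

    def slice(self, key: str) -> pd.DataFrame:
        """Aggregate over one grouping key: income_group, region or world."""
        return aggregate_estimates(self.countries, key)

    def verify_aggregates(self, rtol: float = 1e-12) -> None:
        """Check every aggregate equals the sum of its members."""
        agg = self.aggregates
        world = self.countries[_numeric_columns()].sum()
        for key in ("income_group", "region"):
            part = self.slice(key)[_numeric_columns()].sum()
            if not np.allclose(part, world, rtol=rtol):
                raise ValidationError(f"aggregates over {key} do not partition world")
        if not np.allclose(agg.loc["World", _numeric_columns()], world, rtol=rtol):
            raise ValidationError("world aggregate does not equal the country sum")


def aggregate_estimates(countries: pd.DataFrame, key: str) -> pd.DataFrame:
    """Component-wise sums over member countries for one grouping key."""
    if countries.empty:
        raise ValidationError("cannot aggregate an empty estimate table")
    num = _numeric_columns()
    if key == "world":
        out = countries[num].sum().to_frame().T
        out.index = pd.Index(["World"], name="group")
        return out
    if key not in ("income_group", "region"):
        raise KeyError(f"unknown grouping key {key!r}")
    order = INCOME_GROUPS if key == "income_group" else REGIONS
    out = countries.groupby(key)[num].sum()
    out.index.name = "group"
    return out.reindex([g for g in order if g in out.index])


# -- prevalence proportions -------------------------------------------------

def crude_prevalence(prevalent: float, population: float) -> float:
    """Prevalence proportion per 1000 population."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return 1000.0 * prevalent / population


def standardised_prevalence(
    band_rates: np.ndarray, std: StandardPopulation = WHO_WORLD_STANDARD
) -> float:
    """Σ_b weight(b) × rate(b): the directly standardised per-1000 rate."""
    band_rates = np.asarray(band_rates, dtype=float)
    if band_rates.shape != (N_BANDS,):
        raise StructuralError(
            f"band rates must have shape ({N_BANDS},), got {band_rates.shape}"
        )
    return float(std.as_array() @ band_rates)


def prevalence_columns(agg_row: pd.Series) -> tuple[float, float]:
    """Crude and WHO-standardised per-1000 prevalence for one aggregate row."""
    pop = np.array([agg_row[f"pop_{k}"] for k in _BAND_KEYS])
    prev = np.array([agg_row[f"preva_{k}"] for k in _BAND_KEYS])
    crude = crude_prevalence(prev.sum(), pop.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        band_rates = np.where(pop > 0, 1000.0 * prev / np.where(pop > 0, pop, 1), 0.0)
    return crude, standardised_prevalence(band_rates)


# -- share tables -----------------------------------------------------------

def share_table(
    estimates: EstimateTable,
    dimension: str,
    measure: str = "prevalent",
) -> pd.DataFrame:
    """Percentage shares of the world total along one dimension.

    ``dimension``: onset_age | attained_age | income | region.
    ``measure``: incident | prevalent. Shares are reported unrounded and
    rounded to the nearest integer (half away from zero); unrounded shares
    across a full partition sum to exactly 100.
    """
    if measure not in ("incident", "prevalent"):
        raise KeyError(f"unknown measure {measure!r}")
    world = estimates.slice("world").iloc[0]
    if dimension in ("onset_age", "attained_age"):
        prefix = {
            ("incident", "onset_age"): "inc",
            ("prevalent", "onset_age"): "prevo",
            ("prevalent", "attained_age"): "preva",
        }.get((measure, dimension))
        if prefix is None:
            raise KeyError("incident cases have no attained-age dimension")
        parts = pd.Series(
            {lbl: world[f"{prefix}_{k}"] for lbl, k in zip(BAND_LABELS, _BAND_KEYS)}
        )
    elif dimension in ("income", "region"):
        key = "income_group" if dimension == "income" else "region"
        prefix = "inc" if measure == "incident" else "preva"
        agg = estimates.slice(key)
        parts = agg[[f"{prefix}_{k}" for k in _BAND_KEYS]].sum(axis=1)
    else:
        raise KeyError(f"unknown dimension {dimension!r}")
    total = float(parts.sum())
    if total <= 0:
        raise ValidationError("world total must be > 0 for share tables")
    share = 100.0 * parts / total
    return pd.DataFrame(
        {"share_pct": share, "share_pct_rounded": round_half_away(share.to_numpy())},
        index=parts.index,
    )


# -- table emitters ---------------------------------------------------------

TABLE1_COLUMNS = (
    ["group"]
    + [f"inc_{k}_thousands" for k in _BAND_KEYS]
    + ["inc_total_thousands"]
    + [f"preva_{k}_thousands" for k in _BAND_KEYS]
    + ["preva_total_thousands", "crude_per_1000", "standardised_per_1000"]
)


def build_table1(estimates: EstimateTable) -> pd.DataFrame:
    """Headline summary: counts in thousands (2 dp) and per-1000 prevalence.

    Rows: World, the four income levels, the six regions. Totals are
    rounded from unrounded sums, so band cells and totals may disagree in
    the last printed digit.
    """
    agg = estimates.aggregates
    expected = [g for g in GROUP_ORDER]
    missing = [g for g in expected if g not in agg.index]
    if missing:
        raise ValidationError(f"missing aggregate rows: {missing}")
    rows = []
    for group in expected:
        r = agg.loc[group]
        inc = np.array([r[f"inc_{k}"] for k in _BAND_KEYS])
        prev = np.array([r[f"preva_{k}"] for k in _BAND_KEYS])
        crude, std = prevalence_columns(r)
        rows.append(
            [group]
            + list(round_half_away(inc / 1e3, 2))
            + [round_half_away(inc.sum() / 1e3, 2)]
            + list(round_half_away(prev / 1e3, 2))
            + [
                round_half_away(prev.sum() / 1e3, 2),
                round_half_away(crude, 2),
                round_half_away(std, 2),
            ]
        )
    return pd.DataFrame(rows, columns=TABLE1_COLUMNS)


def emit_table1(estimates: EstimateTable, path: str | Path) -> None:
    """Write the headline summary CSV (11 rows × 13 columns)."""
    build_table1(estimates).to_csv(path, index=False)


def emit_long_format(estimates: EstimateTable, path: str | Path) -> None:
    """Long CSV (group × band × measure) for downstream plotting."""
    agg = estimates.aggregates
    records = []
    for group, row in agg.iterrows():
        for prefix, measure in (
            ("inc", "incident_by_onset"),
            ("prevo", "prevalent_by_onset"),
            ("preva", "prevalent_by_attained"),
            ("pop", "population"),
        ):
            for lbl, k in zip(BAND_LABELS, _BAND_KEYS):
                records.append(
                    {
                        "group": group,
                        "measure": measure,
                        "band": lbl,
                        "value": row[f"{prefix}_{k}"],
                    }
                )
    pd.DataFrame(records).to_csv(path, index=False)
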