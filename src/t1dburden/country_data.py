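"""Country-level input table: schema, validation, CSV IO, donor assignment.

One row per country: ISO3 code, World Bank income group, UN region,
population per age band, childhood (0-14 y) type 1 diabetes incidence per
100,000 person-years, under-5 child mortality per 1000 live births, and the
provenance of the incidence figure (observed from a registry study, or
extrapolated from a donor country chosen by expert judgement).

The CSV dialect is fixed: UTF-8, "." decimal separator, one row per country,
columns ``iso3,name,income_group,region,pop_0_14,pop_15_39,pop_40_64,
pop_65p,inc_0_14_per100k,inc_source,inc_donor,cm_per1000``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .bands import BAND_LABELS, N_BANDS
from .errors import ChainingError, FormatError, ReferenceError_, ValidationError

logger = logging.getLogger(__name__)

INCOME_GROUPS = ("HIC", "UMIC", "LMIC", "LIC")
REGIONS = ("Africa", "Asia", "Europe", "LAC", "NA", "Oceania")

POP_COLUMNS = ("pop_0_14", "pop_15_39", "pop_40_64", "pop_65p")
COLUMNS = (
    "iso3",
    "name",
    "income_group",
    "region",
    *POP_COLUMNS,
    "inc_0_14_per100k",
    "inc_source",
    "inc_donor",
    "cm_per1000",
)

IncomeGroup = Literal["HIC", "UMIC", "LMIC", "LIC"]
Region = Literal["Africa", "Asia", "Europe", "LAC", "NA", "Oceania"]
IncidenceSource = Literal["observed", "extrapolated", "missing"]


class CountryRecord(BaseModel):
    """One country's demographic and epidemiological inputs.

    ``childhood_incidence`` is cases per 100,000 person-years in ages 0-14;
    ``cm`` is under-5 deaths per 1000 live births. A record whose incidence
    has not yet been assigned carries ``incidence_source="missing"`` and
    ``childhood_incidence=None``; donor assignment fills it in.
    """

    model_config = ConfigDict(frozen=True)

    iso3: str
    name: str
    income_group: IncomeGroup
    region: Region
    population: tuple[float, float, float, float]
    childhood_incidence: float | None = None
    incidence_source: IncidenceSource = "observed"
    donor: str | None = None
    cm: float

    @field_validator("iso3")
    @classmethod
    def _iso3_shape(cls, v: str) -> str:
        if len(v) != 3 or not v.isalpha():
            raise ValueError(f"iso3 must be three letters, got {v!r}")
        return v.upper()

    @field_validator("population")
    @classmethod
    def _population_nonneg(cls, v):
        for label, p in zip(BAND_LABELS, v):
            if not math.isfinite(p) or p < 0:
                raise ValueError(f"population[{label}] must be finite and >= 0, got {p}")
        return v

    @field_validator("cm")
    @classmethod
    def _cm_nonneg(cls, v: float) -> float:
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"cm must be finite and >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _incidence_consistency(self) -> "CountryRecord":
        if self.incidence_source == "missing":
            if self.childhood_incidence is not None:
                raise ValueError("source 'missing' forbids a childhood_incidence value")
            if self.donor is not None:
                raise ValueError("source 'missing' forbids a donor")
        else:
            inc = self.childhood_incidence
            if inc is None or not math.isfinite(inc) or inc < 0:
                raise ValueError(
                    f"childhood_incidence must be finite and >= 0, got {inc}"
                )
            if self.incidence_source == "extrapolated" and self.donor is None:
                raise ValueError("extrapolated incidence requires a donor iso3")
            if self.incidence_source == "observed" and self.donor is not None:
                raise ValueError("observed incidence must not name a donor")
        return self


@dataclass(frozen=True)
class CountryTable:
    """Ordered collection of CountryRecords with unique ISO3 codes."""

    records: tuple[CountryRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.iso3 in seen:
                raise ValidationError(f"duplicate country_id {r.iso3!r}")
            seen.add(r.iso3)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, iso3: str) -> CountryRecord:
        for r in self.records:
            if r.iso3 == iso3:
                return r
        raise KeyError(iso3)

    def validate_references(self) -> None:
        """Check donor references: must exist and must themselves be observed."""
        by_id = {r.iso3: r for r in self.records}
        for r in self.records:
            if r.incidence_source == "extrapolated":
                donor = by_id.get(r.donor)
                if donor is None:
                    raise ReferenceError_(
                        f"{r.iso3}: donor {r.donor!r} not present in table"
                    )
                if donor.incidence_source != "observed":
                    raise ChainingError(
                        f"{r.iso3}: donor {r.donor} is not observed "
                        f"(source={donor.incidence_source}); donor chains are refused"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "iso3": r.iso3,
                "name": r.name,
                "income_group": r.income_group,
                "region": r.region,
                **{c: p for c, p in zip(POP_COLUMNS, r.population)},
                "inc_0_14_per100k": r.childhood_incidence,
                "inc_source": r.incidence_source,
                "inc_donor": r.donor if r.donor is not None else "",
                "cm_per1000": r.cm,
            }
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _record_from_row(row: Mapping, index: int) -> CountryRecord:
    inc_raw = row["inc_0_14_per100k"]
    inc = None if inc_raw in ("", None) or pd.isna(inc_raw) else float(inc_raw)
    donor_raw = row["inc_donor"]
    donor = None if donor_raw in ("", None) or pd.isna(donor_raw) else str(donor_raw)
    try:
        return CountryRecord(
            iso3=str(row["iso3"]),
            name=str(row["name"]),
            income_group=row["income_group"],
            region=row["region"],
            population=tuple(float(row[c]) for c in POP_COLUMNS),
            childhood_incidence=inc,
            incidence_source=row["inc_source"],
            donor=donor,
            cm=float(row["cm_per1000"]),
        )
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"row {index} ({row.get('iso3', '?')}): {exc}") from exc


def read_country_table(path: str | Path, strict: bool = True) -> CountryTable:
    """Read and validate a country CSV.

    In strict mode any invariant violation raises; in lenient mode offending
    rows are dropped and each drop is logged with its reason. ``NA`` is a
    legitimate region code (North America), so pandas' default NaN sentinels
    are disabled and only the empty string marks a missing value.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[CountryRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        try:
            rec = _record_from_row(row, idx)
            if rec.iso3 in seen:
                raise ValidationError(f"row {idx}: duplicate country_id {rec.iso3!r}")
        except ValidationError as exc:
            if strict:
                raise
            logger.warning("dropping row %d: %s", idx, exc)
            continue
        seen.add(rec.iso3)
        records.append(rec)

    table = CountryTable(records=tuple(records), provenance=str(path))
    try:
        table.validate_references()
    except (ReferenceError_, ChainingError):
        if strict:
            raise
        by_id = {r.iso3: r for r in table.records}
        kept = []
        for r in table.records:
            if r.incidence_source == "extrapolated":
                donor = by_id.get(r.donor)
                if donor is None or donor.incidence_source != "observed":
                    logger.warning("dropping %s: unresolvable donor %s", r.iso3, r.donor)
                    continue
            kept.append(r)
        table = CountryTable(records=tuple(kept), provenance=str(path))
    return table


def write_country_table(table: CountryTable, path: str | Path) -> None:
    """Write a CountryTable as CSV, numeric fields at full precision."""
    df = table.to_frame()
    # repr-precision floats so read(write(t)) == t field-by-field
    df.to_csv(path, index=False, float_format=None)


def assign_missing_incidence(
    table: CountryTable, donor_map: Mapping[str, str]
) -> CountryTable:
    """Fill incidence gaps by copying each mapped country's rate from its donor.

    The choice of donor (geographical proximity, income, ethnicity, study
    quality) is expert judgement supplied as data, not computed here. Donors
    must be observed; chains (donor itself extrapolated) are refused because
    no chaining rule is defined. Unmapped countries pass through unchanged;
    the operation is idempotent for a fixed map.
    """
    by_id = {r.iso3: r for r in table.records}
    for target, donor_id in donor_map.items():
        if target not in by_id:
            raise ReferenceError_(f"mapped country {target!r} not present in table")
        if donor_id not in by_id:
            raise ReferenceError_(f"donor {donor_id!r} not present in table")
        if by_id[donor_id].incidence_source != "observed":
            raise ChainingError(
                f"donor {donor_id} for {target} is not observed; refusing chained donors"
            )

    new_records = []
    for r in table.records:
        if r.iso3 in donor_map:
            donor = by_id[donor_map[r.iso3]]
            r = r.model_copy(
                update={
                    "childhood_incidence": donor.childhood_incidence,
                    "incidence_source": "extrapolated",
                    "donor": donor.iso3,
                }
            )
        new_records.append(r)
    return CountryTable(records=tuple(new_records), provenance=table.provenance)
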