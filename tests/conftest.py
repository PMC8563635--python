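import numpy as np
import pytest

from t1dburden import (
    CountryRecord,
    CountryTable,
    DurationParams,
    ModelInputs,
    RATIO_PRESETS,
    SyntheticConfig,
    assign_missing_incidence,
    generate_country_table,
    generate_survival_schedule,
)


@pytest.fixture(scope="session")
def duration_params():
    return DurationParams()


@pytest.fixture(scope="session")
def schedule(duration_params):
    return generate_survival_schedule(7, duration_params)


@pytest.fixture()
def small_table():
    """Three hand-built countries: observed HIC, observed LIC, extrapolated."""
    recs = (
        CountryRecord(
            iso3="FIN",
            name="Finlandia",
            income_group="HIC",
            region="Europe",
            population=(9e5, 1.7e6, 1.8e6, 1.2e6),
            childhood_incidence=60.0,
            incidence_source="observed",
            cm=2.0,
        ),
        CountryRecord(
            iso3="MLW",
            name="Malawia",
            income_group="LIC",
            region="Africa",
            population=(8e6, 7e6, 3e6, 0.6e6),
            childhood_incidence=1.5,
            incidence_source="observed",
            cm=55.0,
        ),
        CountryRecord(
            iso3="NBR",
            name="Neighbouria",
            income_group="LIC",
            region="Africa",
            population=(5e6, 4e6, 2e6, 0.4e6),
            childhood_incidence=1.5,
            incidence_source="extrapolated",
            donor="MLW",
            cm=80.0,
        ),
    )
    return CountryTable(records=recs, provenance="unit-test fixture")


@pytest.fixture(scope="session")
def world_inputs(schedule, duration_params):
    """A resolved 200-country synthetic world ready for estimation."""
    table, donor_map = generate_country_table(SyntheticConfig(seed=11))
    table = assign_missing_incidence(table, donor_map)
    return ModelInputs(
        table=table,
        schedule=schedule,
        ratios=RATIO_PRESETS["core"],
        duration_params=duration_params,
    )
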