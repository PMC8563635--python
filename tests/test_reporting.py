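import numpy as np
import pandas as pd
import pytest

from t1dburden import (
    WHO_WORLD_STANDARD,
    EstimateTable,
    StandardPopulation,
    build_table1,
    compute_estimates,
    crude_prevalence,
    emit_table1,
    round_half_away,
    share_table,
    standardised_prevalence,
)
from t1dburden.errors import ValidationError
from t1dburden.reporting import WHO_STANDARD_5YR, aggregate_estimates


@pytest.fixture(scope="module")
def world_estimates(world_inputs):
    return compute_estimates(world_inputs)


class TestWhoStandard:
    def test_four_band_weights_sum_to_one(self):
        assert sum(WHO_WORLD_STANDARD.weights) == pytest.approx(1.0, abs=1e-9)
        assert all(w > 0 for w in WHO_WORLD_STANDARD.weights)

    def test_aggregation_matches_published_five_year_groups(self):
        # normalised sums of the published 5-year proportions per band
        total = sum(WHO_STANDARD_5YR.values())
        child = (
            WHO_STANDARD_5YR["0-4"]
            + WHO_STANDARD_5YR["5-9"]
            + WHO_STANDARD_5YR["10-14"]
        ) / total
        assert WHO_WORLD_STANDARD.weights[0] == pytest.approx(child, rel=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            StandardPopulation(weights=(0.3, 0.3, 0.3, 0.2))


class TestRates:
    def test_crude_prevalence_unit_arithmetic(self):
        assert crude_prevalence(9000, 3_000_000) == pytest.approx(3.0)
        assert crude_prevalence(0, 1000) == 0.0
        with pytest.raises(ValueError):
            crude_prevalence(10, 0)

    def test_equal_band_rates_reproduce_crude(self):
        assert standardised_prevalence(np.full(4, 2.5)) == pytest.approx(2.5)

    def test_single_band_rate_scales_by_weight(self):
        rates = np.array([0.0, 0.0, 4.0, 0.0])
        expected = 4.0 * WHO_WORLD_STANDARD.weights[2]
        assert standardised_prevalence(rates) == pytest.approx(expected)

    def test_standard_structured_population_gives_crude_equal_standardised(self):
        # a population whose age structure equals the standard: crude == standardised
        pop = 1e6 * np.asarray(WHO_WORLD_STANDARD.weights)
        prev = np.array([200.0, 1500.0, 2200.0, 900.0])
        band_rates = 1000.0 * prev / pop
        crude = crude_prevalence(prev.sum(), pop.sum())
        assert standardised_prevalence(band_rates) == pytest.approx(crude, rel=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "x,d,expected",
        [(2.5, 0, 3.0), (-2.5, 0, -3.0), (0.125, 2, 0.13), (234.715, 2, 234.72)],
    )
    def test_round_half_away_from_zero(self, x, d, expected):
        assert round_half_away(x, d) == expected


class TestAggregation:
    def test_single_country_group_equals_that_country(self, world_estimates):
        one = world_estimates.countries.iloc[[0]]
        agg = aggregate_estimates(one, "income_group")
        np.testing.assert_allclose(
            agg.iloc[0].to_numpy(dtype=float),
            one.drop(columns=["iso3", "income_group", "region"])
            .iloc[0]
            .to_numpy(dtype=float),
        )

    def test_partition_property_income_and_region_sum_to_world(self, world_estimates):
        world_estimates.verify_aggregates()
        world = world_estimates.slice("world").iloc[0]
        for key in ("income_group", "region"):
            part = world_estimates.slice(key).sum()
            np.testing.assert_allclose(
                part.to_numpy(dtype=float), world.to_numpy(dtype=float), rtol=1e-12
            )

    def test_unknown_grouping_key_rejected(self, world_estimates):
        with pytest.raises(KeyError):
            world_estimates.slice("hemisphere")


class TestShareTable:
    def test_full_partition_shares_sum_to_100(self, world_estimates):
        for dim, measure in (
            ("attained_age", "prevalent"),
            ("onset_age", "incident"),
            ("income", "incident"),
            ("region", "prevalent"),
        ):
            shares = share_table(world_estimates, dim, measure)
            assert shares["share_pct"].sum() == pytest.approx(100.0, abs=1e-9)
            assert abs(shares["share_pct_rounded"].sum() - 100.0) <= 1.0 + 1e-9

    def test_single_group_world_is_100(self, world_inputs):
        from t1dburden import ModelInputs

        one = world_inputs.table.records[:1]
        from t1dburden.country_data import CountryTable

        inputs = ModelInputs(
            table=CountryTable(records=one),
            schedule=world_inputs.schedule,
            ratios=world_inputs.ratios,
            duration_params=world_inputs.duration_params,
        )
        est = compute_estimates(inputs)
        shares = share_table(est, "income", "prevalent")
        assert shares["share_pct"].iloc[0] == pytest.approx(100.0)


class TestTable1:
    def test_layout_contract_11_rows_13_columns(self, world_estimates, tmp_path):
        path = tmp_path / "table1.csv"
        emit_table1(world_estimates, path)
        df = pd.read_csv(path, keep_default_na=False)
        assert df.shape == (11, 13)
        assert list(df["group"]) == [
            "World", "HIC", "UMIC", "LMIC", "LIC",
            "Africa", "Asia", "Europe", "LAC", "NA", "Oceania",
        ]

    def test_rounding_contract_cells_match_unrounded_within_half_ulp(
        self, world_estimates, tmp_path
    ):
        path = tmp_path / "table1.csv"
        emit_table1(world_estimates, path)
        df = pd.read_csv(path, keep_default_na=False).set_index("group")
        agg = world_estimates.aggregates
        for k_csv, k_agg in (
            ("inc_0_14_thousands", "inc_0_14"),
            ("preva_65p_thousands", "preva_65p"),
        ):
            np.testing.assert_allclose(
                df[k_csv].to_numpy(),
                agg[k_agg].to_numpy() / 1e3,
                atol=0.005 + 1e-12,
            )

    def test_world_row_dominates_every_subrow(self, world_estimates):
        t1 = build_table1(world_estimates).set_index("group")
        counts = [c for c in t1.columns if c.endswith("_thousands")]
        world = t1.loc["World", counts]
        for group in t1.index[1:]:
            assert (t1.loc[group, counts] <= world + 1e-12).all()

    def test_band_cells_reconcile_with_total_within_rounding(self, world_estimates):
        t1 = build_table1(world_estimates).set_index("group")
        for prefix in ("inc", "preva"):
            bands = [f"{prefix}_{k}_thousands" for k in ("0_14", "15_39", "40_64", "65p")]
            resid = (t1[bands].sum(axis=1) - t1[f"{prefix}_total_thousands"]).abs()
            assert (resid <= 0.02 + 1e-9).all()
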