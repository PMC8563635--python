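#!/usr/bin/env python
"""Run the core burden model on the generated inputs and report headline numbers.

Reads results/inputs/ (run 01_generate_inputs.py first), applies donor
assignment, the incidence scaling ratios, the child-mortality penalty and
the steady-state identity P = I × D, allocates prevalent cases to attained
ages, and writes per-country estimates, the 11-row summary table and share
tables under results/core/.
"""

from pathlib import Path

import pandas as pd

from t1dburden import (
    DurationParams,
    ModelInputs,
    RATIO_PRESETS,
    SurvivalSchedule,
    assign_missing_incidence,
    build_table1,
    compute_estimates,
    emit_table1,
    read_country_table,
    share_table,
)
from t1dburden.reporting import emit_long_format

IN = Path("results/inputs")
OUT = Path("results/core")


def load_inputs() -> ModelInputs:
    table = read_country_table(IN / "countries_raw.csv")
    donors = pd.read_csv(IN / "donor_map.csv", keep_default_na=False)
    donor_map = dict(zip(donors["iso3"], donors["donor"]))
    table = assign_missing_incidence(table, donor_map)
    return ModelInputs(
        table=table,
        schedule=SurvivalSchedule.from_yaml(IN / "survival_schedule.yaml"),
        ratios=RATIO_PRESETS["core"],
        duration_params=DurationParams(),
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs()
    est = compute_estimates(inputs)
    est.verify_aggregates()

    est.countries.to_csv(OUT / "estimates_by_country.csv", index=False)
    emit_table1(est, OUT / "table1.csv")
    emit_long_format(est, OUT / "aggregates_long.csv")
    for dim, measure in (
        ("attained_age", "prevalent"),
        ("onset_age", "incident"),
        ("income", "incident"),
        ("income", "prevalent"),
        ("region", "prevalent"),
    ):
        share_table(est, dim, measure).to_csv(OUT / f"shares_{measure}_{dim}.csv")

    t1 = build_table1(est).set_index("group")
    world = t1.loc["World"]
    print(f"world incident cases: {world['inc_total_thousands']:.2f} thousand/yr")
    print(f"world prevalent cases: {world['preva_total_thousands']:.2f} thousand")
    print(f"crude prevalence {world['crude_per_1000']:.2f} per 1000, "
          f"standardised {world['standardised_per_1000']:.2f} per 1000")
    shares = share_table(est, "attained_age", "prevalent")["share_pct_rounded"]
    print("prevalent cases by attained age (%):",
          ", ".join(f"{b}: {s:.0f}" for b, s in shares.items()))


if __name__ == "__main__":
    main()
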