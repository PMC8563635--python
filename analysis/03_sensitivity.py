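#!/usr/bin/env python
"""Run the four sensitivity scenarios and tabulate changes against the core.

Scenarios (configs/*.yaml): penalty off, reduced mean duration, and two
alternative child→adult incidence scalings. Writes per-scenario percentage
changes by world/income/region to results/sensitivity/.
"""

from importlib import util as _util
from pathlib import Path

import pandas as pd

from t1dburden import ScenarioSpec, compare_to_core, compute_estimates, run_scenario

# reuse the input loader from the core-estimates driver
_spec = _util.spec_from_file_location(
    "core_estimates", Path(__file__).parent / "02_core_estimates.py"
)
_core = _util.module_from_spec(_spec)
_spec.loader.exec_module(_core)

OUT = Path("results/sensitivity")
CONFIGS = sorted(Path("configs").glob("*.yaml"))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = _core.load_inputs()
    core = compute_estimates(inputs)

    summary = []
    for cfg in CONFIGS:
        spec = ScenarioSpec.from_yaml(cfg)
        scen = run_scenario(inputs, spec)
        frames = [compare_to_core(core, scen, lvl)
                  for lvl in ("world", "income_group", "region")]
        table = pd.concat(frames)
        slug = spec.name.replace(" ", "_")
        table.to_csv(OUT / f"{slug}_vs_core.csv")
        world = table.iloc[0]
        summary.append((spec.name, world["incident_change_pct"],
                        world["prevalent_change_pct"]))
        print(f"{spec.name}: incident {world['incident_change_pct']:+.1f}%, "
              f"prevalent {world['prevalent_change_pct']:+.1f}% (world)")

    pd.DataFrame(
        summary, columns=["scenario", "incident_change_pct", "prevalent_change_pct"]
    ).to_csv(OUT / "summary.csv", index=False)


if __name__ == "__main__":
    main()
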