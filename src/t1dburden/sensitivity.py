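"""Named sensitivity scenarios and comparison against the core model.

Four scenarios probe the model's main assumptions: switching the
child-mortality penalty off ('ignoring penalty function'), shrinking all
maximum mean durations ('reduced mean duration'), and two alternative
child→adult incidence scalings ('changed incidence scaling 1' with reduced
adult ratios and 'changed incidence scaling 2' with all adult bands at
0.5). A scenario re-runs the full pipeline with its overrides applied and
everything else identical to the core configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ScenarioError
from .incidence_model import RATIO_PRESETS, ScalingRatios

if TYPE_CHECKING:
    from .pipeline import ModelInputs
    from .reporting import EstimateTable


class ScenarioSpec(BaseModel):
    """Overrides applied on top of the core configuration.

    ``override_penalty`` forces a fixed penalty value for every country
    (0 disables the penalty); ``duration_scale`` multiplies all maximum
    mean durations; ``ratio_set`` replaces the incidence scaling ratios
    (a preset name or four explicit values). At least one override must be
    present.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    override_penalty: float | None = None
    duration_scale: float | None = None
    ratio_set: str | tuple[float, float, float, float] | None = None

    @model_validator(mode="after")
    def _at_least_one_override(self) -> "ScenarioSpec":
        if (
            self.override_penalty is None
            and self.duration_scale is None
            and self.ratio_set is None
        ):
            raise ValueError(f"scenario {self.name!r} specifies no override")
        if self.override_penalty is not None and not 0 <= self.override_penalty <= 1:
            raise ValueError("override_penalty must lie in [0, 1]")
        if self.duration_scale is not None and self.duration_scale <= 0:
            raise ValueError("duration_scale must be > 0")
        return self

    def ratios(self) -> ScalingRatios | None:
        if self.ratio_set is None:
            return None
        if isinstance(self.ratio_set, str):
            if self.ratio_set not in RATIO_PRESETS:
                raise ScenarioError(f"unknown ratio preset {self.ratio_set!r}")
            return RATIO_PRESETS[self.ratio_set]
        return ScalingRatios(tuple(self.ratio_set), name=self.name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ScenarioError(f"{path}: scenario file must be a mapping")
        if isinstance(doc.get("ratio_set"), list):
            doc["ratio_set"] = tuple(doc["ratio_set"])
        try:
            return cls(**doc)
        except (ValueError, TypeError) as exc:
            raise ScenarioError(f"{path}: {exc}") from exc


#: The four canonical scenarios. The adult ratios of scaling 1 and the
#: duration multiplier of 'reduced mean duration' are placeholders (the
#: original values are not published in accessible form); scaling 2 (all
#: adult bands at 0.5) is as published.
CANONICAL_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec(name="ignoring penalty function", override_penalty=0.0),
    ScenarioSpec(name="reduced mean duration", duration_scale=0.72),
    ScenarioSpec(
        name="changed incidence scaling 1", ratio_set=(1.00, 0.35, 0.20, 0.15)
    ),
    ScenarioSpec(
        name="changed incidence scaling 2", ratio_set=(1.00, 0.50, 0.50, 0.50)
    ),
)


def run_scenario(inputs: "ModelInputs", spec: ScenarioSpec) -> "EstimateTable":
    """Re-run the full pipeline with the scenario's overrides applied."""
    from .pipeline import compute_estimates  # local import breaks the cycle

    return compute_estimates(
        inputs,
        ratios=spec.ratios(),
        override_penalty=spec.override_penalty,
        duration_scale=spec.duration_scale,
    )


def compare_to_core(
    core: "EstimateTable", scenario: "EstimateTable", level: str = "world"
) -> pd.DataFrame:
    """Percentage change (scenario − core) / core × 100 per group.

    Positive means the scenario increases the estimate. Groups with a zero
    core value are flagged with NaN rather than silently dropped.
    """
    core_agg = core.slice(level)
    scen_agg = scenario.slice(level)
    if not core_agg.index.equals(scen_agg.index):
        raise ScenarioError("core and scenario aggregates have different groups")
    from .reporting import _BAND_KEYS  # shared band key order

    out = pd.DataFrame(index=core_agg.index)
    for measure, prefix in (("incident", "inc"), ("prevalent", "preva")):
        cols = [f"{prefix}_{k}" for k in _BAND_KEYS]
        core_total = core_agg[cols].sum(axis=1)
        scen_total = scen_agg[cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            change = 100.0 * (scen_total - core_total) / core_total
        out[f"{measure}_change_pct"] = change.where(core_total > 0, np.nan)
    return out
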