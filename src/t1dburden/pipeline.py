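"""End-to-end orchestration: inputs → estimates → reports, reproducibly.

The pipeline executes the estimation chain: load or generate the country
table, fill incidence gaps from donors, scale childhood incidence to adult
bands, convert rates to incident counts, apply the child-mortality penalty
to durations, form steady-state prevalence by onset band, allocate to
attained bands, aggregate, and emit the summary tables. A run manifest
(config echo, seed, content hashes of the inputs) makes runs reproducible
and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .bands import DEFAULT_CAP_AGE
from .country_data import (
    CountryTable,
    assign_missing_incidence,
    read_country_table,
    write_country_table,
)
from .duration_model import DurationParams, mean_durations, penalty
from .errors import PipelineError
from .incidence_model import (
    RATIO_PRESETS,
    ScalingRatios,
    compute_incident_cases,
    scale_incidence_rates,
)
from .prevalence_model import (
    SurvivalSchedule,
    allocation_weights,
    prevalence_by_onset,
)
from .reporting import (
    COUNTRY_COLUMNS,
    EstimateTable,
    emit_long_format,
    emit_table1,
    share_table,
)
from .sensitivity import ScenarioSpec, compare_to_core, run_scenario
from .synthetic_data import (
    SyntheticConfig,
    generate_country_table,
    generate_survival_schedule,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelInputs:
    """Everything a model run consumes: data, schedule, parameters."""

    table: CountryTable
    schedule: SurvivalSchedule
    ratios: ScalingRatios
    duration_params: DurationParams
    tail_truncate: bool = False


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``synthetic`` selects the country
    table; the survival schedule comes from ``schedule_path`` or is
    generated from ``schedule_seed``.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    schedule_path: str | None = None
    schedule_seed: int = 0
    ratio_preset: str = "core"
    duration_params: DurationParams = DurationParams()
    cap_age: float = DEFAULT_CAP_AGE
    tail_truncate: bool = False
    scenario_files: tuple[str, ...] = ()
    out_dir: str = "results/run"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_input(self) -> "RunConfig":
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be given")
        return self


def _stage(stage: str, fn, *args, country_id: str | None = None, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # re-raise with stage context
        raise PipelineError(stage, str(exc), country_id=country_id) from exc


def compute_estimates(
    inputs: ModelInputs,
    ratios: ScalingRatios | None = None,
    override_penalty: float | None = None,
    duration_scale: float | None = None,
) -> EstimateTable:
    """Run the per-country estimation chain and return the estimate table.

    ``ratios`` / ``override_penalty`` / ``duration_scale`` override the
    core configuration for scenario runs; everything else is identical.
    """
    use_ratios = ratios if ratios is not None else inputs.ratios
    params = inputs.duration_params
    if duration_scale is not None:
        params = DurationParams(
            max_duration=tuple(
                m * duration_scale for m in params.max_duration
            ),
            min_duration=params.min_duration,
            penalty_constant=params.penalty_constant,
        )

    rows = []
    for rec in inputs.table:
        if rec.childhood_incidence is None:
            raise PipelineError(
                "scale_incidence",
                "country lacks an incidence value; run donor assignment first",
                country_id=rec.iso3,
            )
        pop = np.asarray(rec.population)
        rates = _stage(
            "scale_incidence",
            scale_incidence_rates,
            rec.childhood_incidence,
            use_ratios,
            country_id=rec.iso3,
        )
        incident = _stage(
            "incident_cases", compute_incident_cases, rates, pop, country_id=rec.iso3
        )
        pen = (
            override_penalty
            if override_penalty is not None
            else _stage("penalty", penalty, rec.cm, params, country_id=rec.iso3)
        )
        durations = _stage(
            "durations", mean_durations, pen, params, country_id=rec.iso3
        )
        p_onset = _stage(
            "prevalence_by_onset",
            prevalence_by_onset,
            incident,
            durations,
            country_id=rec.iso3,
        )
        W = _stage(
            "attained_allocation",
            allocation_weights,
            inputs.schedule,
            durations=durations,
            tail_truncate=inputs.tail_truncate,
            country_id=rec.iso3,
        )
        p_att = p_onset @ W
        rows.append(
            [rec.iso3, rec.income_group, rec.region]
            + list(pop)
            + list(incident)
            + list(p_onset)
            + list(p_att)
        )
    frame = pd.DataFrame(rows, columns=list(COUNTRY_COLUMNS))
    return EstimateTable(countries=frame)


def load_inputs(config: RunConfig) -> tuple[ModelInputs, dict[str, str]]:
    """Resolve a RunConfig into concrete model inputs (plus any donor map)."""
    donor_map: dict[str, str] = {}
    if config.synthetic is not None:
        table, donor_map = _stage(
            "generate_inputs", generate_country_table, config.synthetic
        )
    else:
        table = _stage("read_inputs", read_country_table, config.input_path)

    if config.schedule_path is not None:
        schedule = _stage(
            "read_schedule", SurvivalSchedule.from_yaml, config.schedule_path
        )
    else:
        schedule = _stage(
            "generate_schedule",
            generate_survival_schedule,
            config.schedule_seed,
            config.duration_params,
            config.cap_age,
        )

    if donor_map:
        table = _stage("assign_donors", assign_missing_incidence, table, donor_map)

    inputs = ModelInputs(
        table=table,
        schedule=schedule,
        ratios=RATIO_PRESETS[config.ratio_preset],
        duration_params=config.duration_params,
        tail_truncate=config.tail_truncate,
    )
    return inputs, donor_map


def _content_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all outputs; returns the out dir.

    Outputs: the resolved country table, the survival schedule, per-country
    estimates, the headline summary table, long-format aggregates, share
    tables, per-scenario comparison tables, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    inputs, donor_map = load_inputs(config)

    table_path = out / "countries_resolved.csv"
    write_country_table(inputs.table, table_path)
    schedule_path = out / "survival_schedule.yaml"
    inputs.schedule.to_yaml(schedule_path)

    core = _stage("estimate", compute_estimates, inputs)
    core.verify_aggregates()
    core.countries.to_csv(out / "estimates_by_country.csv", index=False)
    _stage("report_table1", emit_table1, core, out / "table1.csv")
    emit_long_format(core, out / "aggregates_long.csv")
    for dimension, measure in (
        ("attained_age", "prevalent"),
        ("onset_age", "incident"),
        ("income", "incident"),
        ("income", "prevalent"),
        ("region", "incident"),
        ("region", "prevalent"),
    ):
        share_table(core, dimension, measure).to_csv(
            out / f"shares_{measure}_{dimension}.csv"
        )

    scenario_names = []
    for sf in config.scenario_files:
        spec = _stage("scenario_spec", ScenarioSpec.from_yaml, sf)
        scen = _stage(f"scenario:{spec.name}", run_scenario, inputs, spec)
        slug = spec.name.replace(" ", "_")
        scenario_names.append(spec.name)
        frames = []
        for level in ("world", "income_group", "region"):
            frames.append(compare_to_core(core, scen, level))
        pd.concat(frames).to_csv(out / f"scenario_{slug}_vs_core.csv")

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "donor_map": donor_map,
        "scenarios": scenario_names,
        "input_hashes": {
            "countries_resolved.csv": _content_hash(table_path.read_text()),
            "survival_schedule.yaml": _content_hash(schedule_path.read_text()),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
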