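"""File-format plumbing and the end-to-end pipeline.

All tabular artifacts are UTF-8 CSV with a header row and dot-decimal
numbers; structured configs are JSON.  Source tables in this domain often
carry comma decimals ("50,85"), so the readers normalize comma-decimal text
columns to numbers on ingest.  A pipeline run writes a manifest (inputs,
seed, package version, SHA-256 hashes of every artifact) so that a run is
reproducible and any input or seed change is visible as a hash change.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .emptying import PulseSchedule
from .errors import ConfigurationError, MidaError
from .metrics import GroupComparison, MetricsResult, compare_groups, metrics_table
from .protocol import (
    FluidRecipe,
    FoodSpec,
    SamplingPlan,
    VolumePlan,
    default_sampling_plan,
    make_fluid_recipe,
    plan_fluid_volumes,
)
from .simulator import KineticParams, SimTimeSeries
from .synthetic import (
    PRESET_CLASSES,
    ExperimentDesign,
    NoiseModel,
    generate_experiment,
    preset_design,
    standard_schedule,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_recipe_json",
    "read_recipe_json",
    "write_recipes_csv",
    "write_volume_plan",
    "write_metrics_csv",
    "write_comparisons_csv",
    "write_sampling_plan_csv",
    "food_from_json",
    "food_to_json",
    "kinetics_from_json",
    "sha256_file",
]

log = logging.getLogger("midasim")


# ---------------------------------------------------------------------------
# primitive readers / writers
# ---------------------------------------------------------------------------

def _normalize_decimals(df: pd.DataFrame) -> pd.DataFrame:
    """Convert comma-decimal text columns ("50,85") to floats, in place."""
    for col in df.columns:
        if df[col].dtype == object:
            converted = pd.to_numeric(
                df[col].astype(str).str.replace(",", ".", regex=False), errors="coerce"
            )
            if converted.notna().all():
                df[col] = converted
    return df


def read_timeseries_csv(path: str | Path) -> SimTimeSeries:
    ts = SimTimeSeries.from_csv(path)
    ts.samples = _normalize_decimals(ts.samples)
    return ts


def write_timeseries_csv(ts: SimTimeSeries, path: str | Path) -> Path:
    ts.to_csv(path)
    return Path(path)


def write_schedule_csv(schedule: PulseSchedule, path: str | Path) -> Path:
    schedule.to_frame().to_csv(path, index=False)
    return Path(path)


def read_schedule_csv(path: str | Path,
                      pulses_per_min: float = 4.0) -> PulseSchedule:
    df = _normalize_decimals(pd.read_csv(path))
    return PulseSchedule.from_frame(df, pulses_per_min=pulses_per_min)


def write_recipe_json(recipe: FluidRecipe, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(recipe), indent=2), encoding="utf-8")
    return path


def read_recipe_json(path: str | Path) -> FluidRecipe:
    from .protocol import EnzymeDose

    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    raw["enzymes"] = tuple(EnzymeDose(**e) for e in raw["enzymes"])
    return FluidRecipe(**raw)


def write_recipes_csv(recipes: list[FluidRecipe], path: str | Path) -> Path:
    rows = [row for r in recipes for row in r.to_rows()]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_volume_plan(plan: VolumePlan, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(
            [{"fluid": "plan", "component": k, "amount": v, "unit": "ml"}
             for k, v in plan.to_dict().items()]
        ).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(plan.to_dict(), indent=2), encoding="utf-8")
    return path


def write_sampling_plan_csv(plan: SamplingPlan, path: str | Path) -> Path:
    pd.DataFrame([dataclasses.asdict(e) for e in plan.events]).to_csv(path, index=False)
    return Path(path)


def write_metrics_csv(result: MetricsResult, path: str | Path) -> Path:
    """One row per timepoint x replicate, followed by a means/SD block."""
    path = Path(path)
    per = result.per_sample.copy()
    per.insert(0, "block", "sample")
    summ = result.summary.copy()
    summ.insert(0, "block", "summary")
    pd.concat([per, summ], ignore_index=True).to_csv(path, index=False)
    return path


def write_comparisons_csv(comparisons: list[GroupComparison], path: str | Path) -> Path:
    rows = [{
        "time_min": c.time_min, "column": c.column,
        "mean_A": c.mean_a, "sd_A": c.sd_a, "mean_B": c.mean_b, "sd_B": c.sd_b,
        "t": c.t_statistic, "p": c.p_value,
        "sig05": c.significant_05, "sig01": c.significant_01,
        "zero_variance": c.zero_variance,
    } for c in comparisons]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def food_to_json(food: FoodSpec, path: str | Path, food_class: str = "") -> Path:
    path = Path(path)
    d = dataclasses.asdict(food)
    if food_class:
        d["food_class"] = food_class
    path.write_text(json.dumps(d, indent=2), encoding="utf-8")
    return path


def food_from_json(path: str | Path) -> tuple[FoodSpec, str]:
    """Read a food spec; returns (FoodSpec, food_class) — class may be ''."""
    path = Path(path)
    if not path.exists():
        raise MidaError(f"food spec not found: {path}")
    raw = json.loads(path.read_text(encoding="utf-8"))
    food_class = raw.pop("food_class", "")
    return FoodSpec(**raw), food_class


def kinetics_from_json(path: str | Path) -> KineticParams:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return KineticParams(**raw)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full plan→schedule→simulate→metrics pipeline run.

    ``foods`` are preset class names (see
    :data:`midasim.synthetic.PRESET_CLASSES`) or paths to food-spec JSON
    files carrying a ``food_class`` field.
    """

    foods: tuple[str, ...]
    out_dir: str
    seed: int = 0
    replicates: int = 3
    assay_cv: float = 0.10
    floor_g: float = 0.001
    schedule_source: str = "model"
    sample_basis: str = "aliquot"
    si_source: str = "at_dissolution"
    s_i: float | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.foods:
            raise ConfigurationError("at least one food is required")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")


def _resolve_design(name: str, config: RunConfig) -> ExperimentDesign:
    if name in PRESET_CLASSES:
        design = preset_design(name)
    else:
        food, food_class = food_from_json(name)
        if food_class not in PRESET_CLASSES:
            raise ConfigurationError(
                f"food spec {name} must name a food_class among {PRESET_CLASSES} "
                "so that calibrated kinetics can be attached"
            )
        design = dataclasses.replace(preset_design(food_class), food=food)
    return dataclasses.replace(
        design,
        replicates=config.replicates,
        schedule_source=config.schedule_source,
        sample_basis=config.sample_basis,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the artifact bundle + manifest.

    Per food: volume plan, fluid recipes, sampling plan, pulse schedule,
    replicated run CSV and metrics CSV; a pairwise comparison CSV when
    exactly two foods are given; and a ``manifest.json`` tying everything to
    the config and seed.  Returns the manifest as a dict.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    runs: dict[str, SimTimeSeries] = {}
    total_records = 0

    for i, name in enumerate(config.foods):
        stage = f"food[{i}] {name}"
        try:
            design = _resolve_design(name, config)
            tag = design.food_class if name in PRESET_CLASSES else Path(name).stem
            plan = plan_fluid_volumes(design.food.portion_volume_ml)
            log.info("%s: planned fluids SSF %.1f / SGF %.1f / SIF %.1f ml",
                     tag, plan.ssf_ml, plan.sgf_ml, plan.sif_ml)
            recipe_class = ("rice_starch" if design.food_class.startswith("rice_starch")
                            else design.food_class)
            recipes = [make_fluid_recipe(f, recipe_class) for f in ("SSF", "SGF", "SIF")]
            schedule = standard_schedule(design.food_class, plan, design.schedule_source)
            sampling = (design.sampling_plan if design.sampling_plan is not None
                        else default_sampling_plan())
            log.info("%s: %d sampling events, %d pyloric pulses over %.0f min",
                     tag, len(sampling), sum(r.n_pulses for r in schedule.rows),
                     schedule.horizon_min)

            noise = NoiseModel(assay_cv=config.assay_cv, floor_g=config.floor_g,
                               seed=config.seed + i)
            ts = generate_experiment(design, noise)
            runs[tag] = ts
            total_records += len(ts.samples)
            mt = metrics_table(ts, si_source=config.si_source, s_i=config.s_i)

            artifacts[f"{tag}.volume_plan.json"] = str(write_volume_plan(plan, out / f"{tag}.volume_plan.json"))
            artifacts[f"{tag}.recipes.csv"] = str(write_recipes_csv(recipes, out / f"{tag}.recipes.csv"))
            artifacts[f"{tag}.sampling_plan.csv"] = str(write_sampling_plan_csv(sampling, out / f"{tag}.sampling_plan.csv"))
            artifacts[f"{tag}.schedule.csv"] = str(write_schedule_csv(schedule, out / f"{tag}.schedule.csv"))
            artifacts[f"{tag}.run.csv"] = str(write_timeseries_csv(ts, out / f"{tag}.run.csv"))
            artifacts[f"{tag}.metrics.csv"] = str(write_metrics_csv(mt, out / f"{tag}.metrics.csv"))
        except MidaError as exc:
            raise MidaError(f"pipeline stage failed ({stage}): {exc}") from exc

    if len(runs) == 2:
        (tag_a, ts_a), (tag_b, ts_b) = runs.items()
        times = sorted(set(ts_a.samples["time_min"]) & set(ts_b.samples["time_min"]))
        comps = [compare_groups(ts_a, ts_b, t) for t in times
                 if min((ts_a.samples["time_min"] == t).sum(),
                        (ts_b.samples["time_min"] == t).sum()) >= 2]
        artifacts["comparison.csv"] = str(
            write_comparisons_csv(comps, out / f"{tag_a}_vs_{tag_b}.comparison.csv"))

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_foods": len(config.foods),
        "n_records": total_records,
        "artifacts": {k: sha256_file(v) for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    log.info("wrote %d artifacts and manifest to %s (%d records)",
             len(artifacts), out, total_records)
    return manifest
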