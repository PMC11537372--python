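"""End-to-end orchestration: configuration, stages and the run directory.

A pipeline run executes, in order: scene simulation (or loading), survey
metrics, raster extraction, the factorial model search, the AIC screen,
spatial trends and the association analyses.  Every stage persists its
outputs as CSV inside the run directory, and a machine-readable run log
records seeds, conventions and stage markers so a run is reproducible from
its directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, geo_extract, meta_screen, model_search, spatial_trends
from .geo_extract import BufferSpec
from .survey_metrics import cohort_summary, response_table, summaries_frame, summarize_location
from .synthetic_data import SimulationConfig, SyntheticScene, generate_scene, read_scene, write_scene

logger = logging.getLogger(__name__)

_ALLOWED_BUFFERS = (2, 5, 10)


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    scene: SimulationConfig = None
    scene_directory: str | None = None  # load instead of simulate when set
    buffer_distances: tuple = (2, 5)
    statistics: tuple = geo_extract.STATISTICS
    search: model_search.SearchConfig = None
    convention: str = "standard"
    smoothing_method: str = "GCV"
    trend_response: str = "A_CW"
    dissolved_distance_km: float = 10
    output_directory: str = "run"

    def __post_init__(self) -> None:
        if self.scene is None:
            self.scene = SimulationConfig(seed=self.seed)
        if self.search is None:
            self.search = model_search.SearchConfig(
                cass_distances=(0,) + tuple(self.buffer_distances),
                cass_summaries=("mean", "median"),
                population_distances=(0, self.buffer_distances[0]),
                population_summaries=("mean",),
                population_forms=("linear", "log"),
                settlement_distances=tuple(self.buffer_distances),
                settlement_forms=("linear",),
                allow_joint_2d=False,
            )
        for d in self.buffer_distances:
            if d not in _ALLOWED_BUFFERS:
                raise ValueError(f"buffer distance {d} km not in the allowed set {_ALLOWED_BUFFERS}")
        if self.dissolved_distance_km not in _ALLOWED_BUFFERS:
            raise ValueError("dissolved_distance_km must be one of {2, 5, 10}")
        if self.convention not in ("standard", "as_printed"):
            raise ValueError(f"unknown information-criterion convention {self.convention!r}")
        if self.smoothing_method not in ("GCV", "REML"):
            raise ValueError(f"unknown smoothing method {self.smoothing_method!r}")
        if self.scene_directory is not None and not Path(self.scene_directory).exists():
            raise FileNotFoundError(f"scene directory {self.scene_directory} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = self.scene.to_dict()
        d["search"] = dataclasses.asdict(self.search)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], dict):
            d["scene"] = SimulationConfig.from_dict(d["scene"])
        if "search" in d and isinstance(d["search"], dict):
            sd = {k: tuple(v) if isinstance(v, list) else v for k, v in d["search"].items()}
            known_s = {f.name for f in dataclasses.fields(model_search.SearchConfig)}
            unknown_s = set(sd) - known_s
            if unknown_s:
                raise ValueError(f"unknown search configuration keys: {sorted(unknown_s)}")
            d["search"] = model_search.SearchConfig(**sd)
        for key in ("buffer_distances", "statistics"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


# ----------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> SyntheticScene:
    if config.scene_directory is not None:
        return read_scene(config.scene_directory)
    scene = generate_scene(config.scene)
    write_scene(scene, outdir / "scene")
    return scene


def stage_metrics(scene: SyntheticScene, outdir: Path) -> pd.DataFrame:
    summaries = [summarize_location(sv) for sv in scene.locations]
    summaries_frame(summaries).to_csv(outdir / "location_summaries.csv", index=False)
    cohort_summary(summaries, scene.locations).to_csv(outdir / "cohort_summary.csv", index=False)
    responses = response_table(scene.locations)
    responses.to_csv(outdir / "responses.csv", index=False)
    return responses


def stage_extract(scene: SyntheticScene, config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    all_summaries = []
    for layer in scene.rasters.values():
        all_summaries.extend(geo_extract.extract_points(layer, scene.locations))
        for d in config.buffer_distances:
            stats = ("mean",) if layer.binary else config.statistics
            all_summaries.extend(
                geo_extract.zonal_summaries(layer, scene.locations, BufferSpec(d), stats)
            )
    geo_extract.summaries_frame(all_summaries).to_csv(outdir / "zonal_summaries.csv", index=False)
    covariates = geo_extract.covariate_table(all_summaries)
    covariates.to_csv(outdir / "covariates.csv", index=False)

    cells = geo_extract.dissolved_cells(
        scene.production_raster, scene.locations, config.dissolved_distance_km
    )
    cells.to_csv(outdir / "dissolved_cells.csv", index=False)
    return covariates


def stage_search(config: PipelineConfig, data: pd.DataFrame, outdir: Path):
    specs = model_search.enumerate_model_space(config.search)
    results = model_search.fit_model_space(
        specs, data, convention=config.convention, method=config.smoothing_method
    )
    table = model_search.results_frame(results)
    table.to_csv(outdir / "model_results.csv", index=False)
    ranked, best = model_search.rank_models(results)
    ranked.to_csv(outdir / "model_ranking.csv", index=False)
    model_search.best_model_smooths(best, data).to_csv(outdir / "best_model_smooths.csv", index=False)
    return results, best


def stage_screen(results, outdir: Path) -> pd.DataFrame:
    table = meta_screen.assemble_screen_table(results)
    anova = meta_screen.type2_screen(table)
    anova.to_csv(outdir / "aic_screen.csv", index=False)
    return anova


def stage_trends(
    scene: SyntheticScene, config: PipelineConfig, responses: pd.DataFrame, outdir: Path
) -> None:
    summaries = [summarize_location(sv) for sv in scene.locations]
    frame = summaries_frame(summaries)
    trend = spatial_trends.fit_location_trend(frame, response=config.trend_response, method=config.smoothing_method)
    trend.grid.to_csv(outdir / "trend_location_smooths.csv", index=False)

    cells = pd.read_csv(outdir / "dissolved_cells.csv")
    raster_trend = spatial_trends.fit_raster_trend(cells, method=config.smoothing_method)
    raster_trend.grid.to_csv(outdir / "trend_raster_smooths.csv", index=False)

    anova = spatial_trends.regional_anova(frame)
    anova.to_csv(outdir / "regional_anova.csv", index=False)


def stage_associate(responses: pd.DataFrame, covariates: pd.DataFrame, outdir: Path) -> None:
    merged = responses.merge(covariates, on="location_id", how="left")
    variables = {
        "tot_cassava_area": "tot_cassava_area",
        "tot_cassava_area_w": "tot_cassava_area_w",
        "tot_monoculture_area": "tot_monoculture_area",
        "tot_intercrop_area": "tot_intercrop_area",
        "map_production": geo_extract.covariate_column("production", 0, "mean"),
        "map_harvest_area": geo_extract.covariate_column("harvest", 0, "mean"),
    }
    table = pd.DataFrame({k: merged[v] for k, v in variables.items() if v in merged.columns})
    association.spearman_matrix(table).to_csv(outdir / "spearman_matrix.csv")

    pred_cols = [v for k, v in variables.items() if k.startswith("map_") and v in merged.columns]
    groups = association.presence_groups(merged[pred_cols], merged["presence"].to_numpy(bool))
    groups.to_csv(outdir / "presence_groups.csv", index=False)


def run_pipeline(config: PipelineConfig, output_directory=None) -> Path:
    """Execute every stage, persisting outputs and a run log; returns the run dir."""
    outdir = Path(output_directory if output_directory is not None else config.output_directory)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": config.seed,
        "convention": config.convention,
        "smoothing_method": config.smoothing_method,
        "stages": {},
    }
    dump_config(config, outdir / "config.yaml")

    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            log["stages"][name] = {"status": "failed", "error": str(exc)}
            (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log["stages"][name] = {"status": "ok", "elapsed_s": round(time.perf_counter() - t0, 3)}
        return result

    scene = run_stage("simulate", lambda: stage_simulate(config, outdir))
    responses = run_stage("metrics", lambda: stage_metrics(scene, outdir))
    covariates = run_stage("extract", lambda: stage_extract(scene, config, outdir))
    data = responses.merge(covariates, on="location_id", how="left")
    results, best = run_stage("search", lambda: stage_search(config, data, outdir))
    run_stage("screen", lambda: stage_screen(results, outdir))
    run_stage("trends", lambda: stage_trends(scene, config, responses, outdir))
    run_stage("associate", lambda: stage_associate(responses, covariates, outdir))

    log["n_models"] = len(results)
    log["n_converged"] = int(sum(1 for r in results if r.converged))
    log["best_model"] = {"aic": best.aic, "spec": str(best.spec.key())}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return outdir
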