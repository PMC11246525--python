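"""Orchestration of the three experiments over a (synthetic) study.

Experiments:

* ``run_compare`` — 3 vegetation indices x 2 regressors, each CV-selected and
  scored on a shared 70/30 split (paired comparison);
* ``run_loyo`` — leave-one-year-out validation of one model plus the ±20%
  relative-error band table;
* ``run_maps`` — per-year pixel-level yield maps from the county-trained
  model, validated against county statistics and site observations;
* ``run_timing`` — forward-month (in-season) skill curve.

Each experiment is a pure function of its :class:`RunConfig`; when an output
directory is given, results are written as CSV plus a JSON manifest with the
config and seed, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evaluate as ev
from .features import build_feature_matrix, pixel_feature_table
from .indices import VI_NAMES
from .models import ModelSpec, predict, random_split, tenfold_cv_select, train
from .raster import RasterCube, RasterGrid, write_raster
from .reconstruct import (
    SGParams,
    SeasonSpec,
    fuse,
    monthly_max_composite,
    sg_smooth,
    temporal_interpolate,
)
from .synthdata import SceneConfig, SyntheticScene, derive_vi_cube, generate_scene

__all__ = ["RunConfig", "reconstruct_vi_year", "reconstructed_features",
           "run_compare", "run_loyo", "run_maps", "run_timing"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one experiment over a synthetic scene."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    vi_name: str = "NIRv"
    algorithm: str = "lstm"
    sg: SGParams = field(default_factory=SGParams)
    seed: int = 0
    out_dir: Path | None = None
    lgbm_grid: list | None = None
    lstm_grid: list | None = None
    use_reconstructed: bool = True  # False: model the true (pre-gap) features

    def __post_init__(self) -> None:
        if self.vi_name not in VI_NAMES:
            raise ValueError(f"vi_name must be one of {VI_NAMES}")
        if self.algorithm not in ("lstm", "lgbm"):
            raise ValueError("algorithm must be 'lstm' or 'lgbm'")

    def grid_for(self, algorithm: str):
        return self.lgbm_grid if algorithm == "lgbm" else self.lstm_grid


def _write_manifest(config: RunConfig, out_dir: Path, experiment: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "experiment": experiment,
        "seed": config.seed,
        "vi_name": config.vi_name,
        "algorithm": config.algorithm,
        "sg": dataclasses.asdict(config.sg),
        "scene": dataclasses.asdict(config.scene),
        "use_reconstructed": config.use_reconstructed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def reconstruct_vi_year(
    scene: SyntheticScene, vi_name: str, year: int, sg: SGParams
) -> RasterCube:
    """Full reconstruction for one season: observations -> fused VI cube.

    Fine path: derive the VI from the gappy fine observations, composite to
    monthly maxima.  Coarse path: derive, temporally interpolate, composite,
    SG-smooth.  Fusion then substitutes resampled coarse values into fine
    gaps and smooths the final series.
    """
    season = SeasonSpec(year)
    fine_vi = derive_vi_cube(scene.fine_obs[year], vi_name)
    fine_monthly = monthly_max_composite(fine_vi, season)

    coarse_vi = derive_vi_cube(scene.coarse_obs[year], vi_name)
    coarse_vi = temporal_interpolate(coarse_vi)
    coarse_monthly = monthly_max_composite(coarse_vi, season)
    coarse_smoothed = sg_smooth(temporal_interpolate(coarse_monthly), sg)

    return fuse(fine_monthly, coarse_smoothed, sg).smoothed


def reconstructed_features(
    scene: SyntheticScene, vi_name: str, sg: SGParams
) -> tuple[pd.DataFrame, dict[int, RasterCube]]:
    """County feature matrix (with yields) from fully reconstructed VI cubes."""
    cubes = {
        year: reconstruct_vi_year(scene, vi_name, year, sg)
        for year in scene.config.harvest_years
    }
    fm = build_feature_matrix(cubes, scene.climate, scene.counties, scene.crop_mask,
                              scene.county_yields)
    return fm, cubes


def _feature_matrix(scene: SyntheticScene, config: RunConfig, vi_name: str) -> pd.DataFrame:
    if config.use_reconstructed:
        fm, _ = reconstructed_features(scene, vi_name, config.sg)
        return fm
    if vi_name != "NIRv" and vi_name != scene.config.__dict__.get("target_vi", "NIRv"):
        logger.warning("true-feature mode only carries the scene's target VI")
    return scene.county_table()


def run_compare(config: RunConfig, scene: SyntheticScene | None = None) -> pd.DataFrame:
    """3 VIs x 2 algorithms on a shared 70/30 split: r2 and rmse per cell."""
    scene = scene or generate_scene(config.scene)
    rows = []
    for vi_name in VI_NAMES:
        fm, _ = reconstructed_features(scene, vi_name, config.sg)
        train_fm, test_fm = random_split(fm, seed=config.seed)
        for algorithm in ("lstm", "lgbm"):
            spec = tenfold_cv_select(train_fm, algorithm, grid=config.grid_for(algorithm),
                                     seed=config.seed)
            model = train(train_fm, spec)
            report = ev.metrics(test_fm["yield_kg_ha"].to_numpy(), predict(model, test_fm))
            rows.append({"vi_name": vi_name, "algorithm": algorithm,
                         "r2": report.r2, "rmse": report.rmse, "n_test": report.n})
            logger.info("compare %s/%s: r2=%.3f rmse=%.1f", vi_name, algorithm,
                        report.r2, report.rmse)
    table = pd.DataFrame(rows)
    if config.out_dir is not None:
        _write_manifest(config, Path(config.out_dir), "compare")
        table.to_csv(Path(config.out_dir) / "compare.csv", index=False)
    return table


def run_loyo(config: RunConfig, scene: SyntheticScene | None = None,
             spec: ModelSpec | None = None) -> tuple[ev.LoyoResult, pd.DataFrame]:
    """Leave-one-year-out validation plus the RE band table."""
    scene = scene or generate_scene(config.scene)
    fm = _feature_matrix(scene, config, config.vi_name)
    if spec is None:
        spec = tenfold_cv_select(fm, config.algorithm,
                                 grid=config.grid_for(config.algorithm), seed=config.seed)
    loyo = ev.leave_one_year_out(fm, spec)
    bands = ev.re_by_unit(loyo)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _write_manifest(config, out, "loyo")
        summary = pd.DataFrame(
            [{"year": y, "r2": r.r2, "rmse": r.rmse, "n": r.n} for y, r in loyo.reports.items()]
        )
        summary.to_csv(out / "loyo_by_year.csv", index=False)
        bands.to_csv(out / "re_bands.csv", index=False)
    return loyo, bands


def run_maps(config: RunConfig, scene: SyntheticScene | None = None
             ) -> tuple[ev.EvalReport, ev.EvalReport, dict[int, RasterGrid]]:
    """Pixel-level yield maps per year, validated at county and site level.

    The model is trained on all county rows (the mapping deployment mode),
    then applied to every crop pixel's feature row; county validation pools
    all years, as does site validation.
    """
    scene = scene or generate_scene(config.scene)
    fm, cubes = reconstructed_features(scene, config.vi_name, config.sg)
    spec = tenfold_cv_select(fm, config.algorithm,
                             grid=config.grid_for(config.algorithm), seed=config.seed)
    model = train(fm, spec)

    maps: dict[int, RasterGrid] = {}
    c_obs, c_pred, c_ids, c_years = [], [], [], []
    s_obs, s_pred, s_ids, s_years = [], [], [], []
    county_by_key = {(r.unit_id, r.year): r for r in scene.county_yields}
    site_by_key = {(r.unit_id, r.year): r for r in scene.site_yields}
    for year, cube in cubes.items():
        pixel_fm = pixel_feature_table(cube, scene.climate, scene.crop_mask, year)
        ymap = ev.yield_map(model, pixel_fm, cube.spec)
        maps[year] = ymap
        county_recs = [r for (u, y), r in county_by_key.items() if y == year]
        site_recs = [r for (u, y), r in site_by_key.items() if y == year]
        if len(county_recs) >= 2:
            cr, sr = None, None
            try:
                cr, sr = ev.validate_map(ymap, scene.counties, scene.crop_mask,
                                         county_recs, site_recs)
            except ValueError:
                logger.warning("year %d: too few validation records", year)
            if cr is not None:
                c_obs += cr.records["observed"].tolist()
                c_pred += cr.records["predicted"].tolist()
                c_ids += cr.records["unit_id"].tolist()
                c_years += [year] * cr.n
            if sr is not None:
                s_obs += sr.records["observed"].tolist()
                s_pred += sr.records["predicted"].tolist()
                s_ids += sr.records["unit_id"].tolist()
                s_years += [year] * sr.n
    county_report = ev.metrics(c_obs, c_pred, c_ids, c_years)
    site_report = ev.metrics(s_obs, s_pred, s_ids, s_years)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _write_manifest(config, out, "maps")
        for year, grid in maps.items():
            write_raster(grid, out / f"yield_map_{year}.tif")
        county_report.records.to_csv(out / "map_validation_county.csv", index=False)
        site_report.records.to_csv(out / "map_validation_site.csv", index=False)
    return county_report, site_report, maps


def run_timing(config: RunConfig, scene: SyntheticScene | None = None) -> pd.DataFrame:
    """Forward-month skill curve for the configured VI and algorithm."""
    scene = scene or generate_scene(config.scene)
    fm = _feature_matrix(scene, config, config.vi_name)
    table = ev.forward_month_analysis(fm, config.algorithm,
                                      grid=config.grid_for(config.algorithm),
                                      seed=config.seed)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _write_manifest(config, out, "timing")
        table.to_csv(out / "timing.csv", index=False)
    return table
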