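"""Synthetic winter-wheat scenes: paired fine/coarse VI sensors, climate,
counties, crop mask and yields with the statistical structure the analysis
assumes.

The generator emulates the study design of a 30 m Landsat-like sensor
(sparse revisit, spatially correlated cloud gaps) paired with a ~500 m
MODIS-like sensor (dense revisit, k x k block aggregate of the truth), five
monthly climate variables on a coarser climate grid, a rectangular county
partition with a clumped crop mask, and county/site yields generated from a
stated linear function of the monthly VI and season-mean climate plus
Gaussian noise.  Everything is a pure function of :class:`SceneConfig`
(including the master seed).

Per-pixel truth follows a single-season double-logistic VI curve (October
planting, April peak, May senescence).  Three variance components drive
yield-relevant variation: a scalar per-year anomaly of the seasonal
amplitude (good vs bad years), a static smooth spatial productivity field,
and independent smooth monthly anomaly fields.  The monthly anomalies are
what make month-resolved information identifiable in timing experiments;
the shared amplitude components induce the cross-month correlation real VI
series show.  Default magnitudes are calibrated so county yields land in
the ~4000-8000 kg/ha regime (mean ~6000, sd ~1000) against the default
yield noise sd of 300 kg/ha.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .features import CLIMATE_VARS, ClimateStack, CountyMap, YieldRecord
from .raster import GridSpec, RasterCube, RasterGrid
from .reconstruct import SLOT_NAMES, SeasonSpec

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene",
           "gen_truth_vi", "gen_observations", "gen_counties", "gen_climate", "gen_yields"]

# Seed-stream tags so every component draws from an independent substream.
_TAG_TRUTH, _TAG_OBS, _TAG_COUNTY, _TAG_CLIMATE, _TAG_YIELD, _TAG_SPATIAL = range(1, 7)

_SLOT_MONTHS = (10, 11, 12, 1, 2, 3, 4, 5)

# Monthly climatology Oct..May per climate variable (units: mm, degC, kPa, mm).
_CLIMATOLOGY = {
    "Pr": (30.0, 25.0, 15.0, 10.0, 12.0, 20.0, 35.0, 45.0),
    "Tmin": (8.0, 0.0, -6.0, -8.0, -5.0, 1.0, 8.0, 14.0),
    "Tgap": (12.0, 12.0, 11.0, 11.0, 11.0, 12.0, 13.0, 13.0),  # Tmax - Tmin
    "VPD": (0.9, 0.6, 0.4, 0.35, 0.45, 0.7, 1.1, 1.5),
    "SM": (60.0, 65.0, 70.0, 72.0, 68.0, 60.0, 50.0, 40.0),
}
_CLIMATE_YEAR_SD = {"Pr": 8.0, "Tmin": 1.2, "Tgap": 0.6, "VPD": 0.12, "SM": 8.0}
_CLIMATE_SPATIAL_SD = {"Pr": 4.0, "Tmin": 0.8, "Tgap": 0.4, "VPD": 0.06, "SM": 5.0}
_CLIMATE_GRADIENT = {"Pr": 6.0, "Tmin": 1.5, "Tgap": 0.5, "VPD": 0.15, "SM": -8.0}


@dataclass(frozen=True)
class SceneConfig:
    """All knobs of the synthetic study, with defaults at the study scale:
    100 counties x 20 seasons (>= 2000 county-year records) on a 120x120
    fine grid with a 16x coarse sensor."""

    n_rows: int = 120
    n_cols: int = 120
    pixel_size: float = 1.0
    crs_tag: str = "synthetic"
    coarse_factor: int = 16
    climate_factor: int = 40

    n_years: int = 20
    first_harvest_year: int = 2001
    truth_obs_per_month: int = 4
    fine_obs_per_month: int = 2
    coarse_obs_per_month: int = 4

    cloud_fraction: float = 0.3
    noise_sd: float = 0.02
    cloud_corr_length: float = 10.0

    n_counties: int = 100
    crop_fraction: float = 0.6
    n_sites: int = 13

    # Phenology (VI units; slots indexed 0=Oct .. 7=May).
    base_vi: float = 0.15
    peak_vi: float = 0.75
    greenup_slot: float = 3.5
    senescence_slot: float = 7.6
    greenup_width: float = 0.8
    senescence_width: float = 0.35
    spatial_sd: float = 0.10
    spatial_corr_length: float = 15.0
    year_sd: float = 0.15
    month_anomaly_sd: float = 0.05

    # Yield model (kg/ha); beta magnitudes are set for the NIRv scale of the
    # default target VI so county yields land in the ~4000-8000 kg/ha regime.
    beta0: float = 2600.0
    beta_slots: tuple[float, ...] = (600.0, 750.0, 1000.0, 1350.0, 1950.0, 3150.0, 4650.0, 2300.0)
    gamma: tuple[tuple[str, float], ...] = (
        ("Pr", 6.0), ("Tmax", -80.0), ("Tmin", 40.0), ("VPD", -400.0), ("SM", 3.0)
    )
    sigma_y: float = 300.0
    yield_floor: float = 100.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.coarse_factor < 2:
            raise ValueError("coarse_factor must be >= 2")
        if not 0 <= self.cloud_fraction <= 1:
            raise ValueError("cloud_fraction must lie in [0, 1]")
        if self.peak_vi > 1:
            raise ValueError("peak VI must not exceed 1")
        if len(self.beta_slots) != 8:
            raise ValueError("beta_slots must have 8 entries (Oct..May)")

    @property
    def fine_spec(self) -> GridSpec:
        return GridSpec(0.0, self.n_rows * self.pixel_size, self.pixel_size,
                        self.pixel_size, self.n_rows, self.n_cols, self.crs_tag)

    @property
    def coarse_spec(self) -> GridSpec:
        k = self.coarse_factor
        return GridSpec(0.0, self.n_rows * self.pixel_size, k * self.pixel_size,
                        k * self.pixel_size, -(-self.n_rows // k), -(-self.n_cols // k),
                        self.crs_tag)

    @property
    def climate_spec(self) -> GridSpec:
        # One climate-pixel margin on every side so bilinear resampling to the
        # fine grid is defined everywhere (climate products cover beyond the tile).
        k = self.climate_factor
        return GridSpec(-k * self.pixel_size, (self.n_rows + k) * self.pixel_size,
                        k * self.pixel_size, k * self.pixel_size,
                        -(-self.n_rows // k) + 2, -(-self.n_cols // k) + 2,
                        self.crs_tag)

    @property
    def harvest_years(self) -> list[int]:
        return list(range(self.first_harvest_year, self.first_harvest_year + self.n_years))

    def gamma_dict(self) -> dict[str, float]:
        return dict(self.gamma)


def _rng(config: SceneConfig, tag: int, year: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag, year]))


def _smooth_field(shape: tuple[int, int], sd: float, corr_length: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth Gaussian field with pointwise standard deviation sd."""
    if sd == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=corr_length, mode="reflect")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(shape)


def _season_curve(config: SceneConfig, s: np.ndarray | float) -> np.ndarray:
    """Unit-amplitude double-logistic phenology at continuous slot time s."""
    up = 1.0 / (1.0 + np.exp(-(np.asarray(s, float) - config.greenup_slot) / config.greenup_width))
    down = 1.0 / (1.0 + np.exp(-(config.senescence_slot - np.asarray(s, float)) / config.senescence_width))
    return up * down


def _season_dates(config: SceneConfig, harvest_year: int, per_month: int) -> list[tuple[_dt.date, float]]:
    """(date, continuous slot time) pairs, ``per_month`` per slot."""
    out = []
    for k, m in enumerate(_SLOT_MONTHS):
        y = harvest_year - 1 if m >= 10 else harvest_year
        days = np.linspace(3, 27, per_month).round().astype(int)
        for d in days:
            out.append((_dt.date(y, m, int(d)), k + (d - 1) / 31.0))
    return out


def gen_truth_vi(config: SceneConfig, year: int) -> RasterCube:
    """Dense gap-free VI truth on the fine grid for one season.

    Deterministic per (seed, year); values clipped to [0, 1].
    """
    spec = config.fine_spec
    spatial = _smooth_field(spec.shape, config.spatial_sd, config.spatial_corr_length,
                            _rng(config, _TAG_SPATIAL))
    rng = _rng(config, _TAG_TRUTH, year)
    year_effect = rng.normal(0.0, config.year_sd) if config.year_sd > 0 else 0.0
    anomalies = [
        _smooth_field(spec.shape, config.month_anomaly_sd, config.spatial_corr_length, rng)
        for _ in range(8)
    ]
    amp = (config.peak_vi - config.base_vi) + year_effect + spatial
    dates = _season_dates(config, year, config.truth_obs_per_month)
    values = np.empty((len(dates),) + spec.shape)
    for i, (_, s) in enumerate(dates):
        slot = min(int(s), 7)
        f = _season_curve(config, s)
        values[i] = np.clip(config.base_vi + (amp + anomalies[slot]) * f, 0.0, 1.0)
    return RasterCube.from_arrays(spec, [d for d, _ in dates], values,
                                  np.ones((len(dates),) + spec.shape, bool))


def _block_reduce_mean(arr: np.ndarray, k: int) -> np.ndarray:
    """k x k block means; edge blocks average over the grid intersection."""
    r_edges = np.arange(0, arr.shape[0], k)
    c_edges = np.arange(0, arr.shape[1], k)
    sums = np.add.reduceat(np.add.reduceat(arr, r_edges, axis=0), c_edges, axis=1)
    ones = np.ones(arr.shape)
    counts = np.add.reduceat(np.add.reduceat(ones, r_edges, axis=0), c_edges, axis=1)
    return sums / counts


def gen_observations(truth: RasterCube, config: SceneConfig,
                     year: int = 0) -> tuple[RasterCube, RasterCube]:
    """Sample the truth with a gappy fine sensor and a dense coarse sensor.

    The fine cube takes every (truth_obs_per_month // fine_obs_per_month)-th
    truth date, adds N(0, noise_sd) noise, and blanks a spatially correlated
    cloud mask covering ~cloud_fraction of pixels per date.  The coarse cube
    is the k x k block mean of the truth at the coarse revisit dates, plus
    independent noise, on the coarse grid; it has no gaps.
    """
    rng = _rng(config, _TAG_OBS, year)
    T = len(truth)
    vals = truth.values_array()

    stride_f = max(1, config.truth_obs_per_month // config.fine_obs_per_month)
    fine_idx = list(range(0, T, stride_f))
    fine_vals = vals[fine_idx] + (
        rng.normal(0.0, config.noise_sd, (len(fine_idx),) + truth.spec.shape)
        if config.noise_sd > 0 else 0.0
    )
    fine_ok = np.ones_like(fine_vals, dtype=bool)
    if config.cloud_fraction > 0:
        for i in range(len(fine_idx)):
            cloud = _smooth_field(truth.spec.shape, 1.0, config.cloud_corr_length, rng)
            thresh = np.quantile(cloud, config.cloud_fraction)
            fine_ok[i] = cloud >= thresh
    fine = RasterCube.from_arrays(truth.spec, [truth.timestamps[i] for i in fine_idx],
                                  np.where(fine_ok, fine_vals, 0.0), fine_ok)

    stride_c = max(1, config.truth_obs_per_month // config.coarse_obs_per_month)
    coarse_idx = list(range(0, T, stride_c))
    cspec = config.coarse_spec
    coarse_vals = np.stack([_block_reduce_mean(vals[i], config.coarse_factor) for i in coarse_idx])
    if config.noise_sd > 0:
        coarse_vals = coarse_vals + rng.normal(0.0, config.noise_sd, coarse_vals.shape)
    coarse = RasterCube.from_arrays(cspec, [truth.timestamps[i] for i in coarse_idx],
                                    coarse_vals, np.ones_like(coarse_vals, dtype=bool))
    return fine, coarse


def gen_counties(config: SceneConfig) -> tuple[CountyMap, RasterGrid]:
    """Rectangular county tiling plus a spatially clumped crop mask.

    Every county is guaranteed at least one crop pixel (its central pixel is
    forced into the mask if the clumped draw left it empty).
    """
    spec = config.fine_spec
    n = config.n_counties
    nr = max(d for d in range(1, int(np.sqrt(n)) + 1) if n % d == 0)
    nc = n // nr
    if nr > config.n_rows or nc > config.n_cols:
        raise ValueError("cannot tile the grid into that many counties")
    row_bins = np.minimum((np.arange(config.n_rows) * nr) // config.n_rows, nr - 1)
    col_bins = np.minimum((np.arange(config.n_cols) * nc) // config.n_cols, nc - 1)
    labels = (row_bins[:, None] * nc + col_bins[None, :] + 1).astype(float)
    county_map = CountyMap(
        RasterGrid(spec, labels, np.ones(spec.shape, bool)),
        {i: f"County {i:03d}" for i in range(1, n + 1)},
    )
    rng = _rng(config, _TAG_COUNTY)
    clump = _smooth_field(spec.shape, 1.0, config.spatial_corr_length / 2, rng)
    thresh = np.quantile(clump, 1.0 - config.crop_fraction)
    mask = clump >= thresh
    for cid in range(1, n + 1):
        cells = labels == cid
        if not mask[cells].any():
            rr, cc = np.nonzero(cells)
            mask[rr[len(rr) // 2], cc[len(cc) // 2]] = True
    return county_map, RasterGrid(spec, mask.astype(float), np.ones(spec.shape, bool))


def gen_climate(config: SceneConfig, year: int) -> ClimateStack:
    """Five monthly climate variables for one season on the climate grid.

    Each variable is climatology + planar gradient + scalar year anomaly +
    smooth spatial noise; Tmax = Tmin + a positive temperature gap, so
    Tmax >= Tmin everywhere by construction.  Deterministic per (seed, year).
    """
    spec = config.climate_spec
    rng = _rng(config, _TAG_CLIMATE, year)
    xs = np.linspace(-0.5, 0.5, spec.n_cols)
    ys = np.linspace(-0.5, 0.5, spec.n_rows)
    plane = ys[:, None] + 0.5 * xs[None, :]
    grids: dict[tuple[int, int], dict[str, RasterGrid]] = {}
    season = SeasonSpec(year)
    for k, (yy, mm) in enumerate(season.slots):
        slot: dict[str, RasterGrid] = {}
        fields = {}
        for var in ("Pr", "Tmin", "Tgap", "VPD", "SM"):
            year_anom = rng.normal(0.0, _CLIMATE_YEAR_SD[var])
            spatial = _smooth_field(spec.shape, _CLIMATE_SPATIAL_SD[var],
                                    max(spec.n_rows / 4, 1.0), rng)
            fields[var] = (_CLIMATOLOGY[var][k] + _CLIMATE_GRADIENT[var] * plane
                           + year_anom + spatial)
        fields["Pr"] = np.clip(fields["Pr"], 0.0, None)
        fields["SM"] = np.clip(fields["SM"], 0.0, None)
        fields["VPD"] = np.clip(fields["VPD"], 0.01, None)
        fields["Tgap"] = np.clip(fields["Tgap"], 0.5, None)
        tmax = fields["Tmin"] + fields["Tgap"]
        ones = np.ones(spec.shape, bool)
        slot["Pr"] = RasterGrid(spec, fields["Pr"], ones.copy())
        slot["Tmax"] = RasterGrid(spec, tmax, ones.copy())
        slot["Tmin"] = RasterGrid(spec, fields["Tmin"], ones.copy())
        slot["VPD"] = RasterGrid(spec, fields["VPD"], ones.copy())
        slot["SM"] = RasterGrid(spec, fields["SM"], ones.copy())
        grids[(yy, mm)] = slot
    return ClimateStack(spec=spec, grids=grids)


def gen_yields(
    county_features: pd.DataFrame,
    config: SceneConfig,
    site_features: pd.DataFrame | None = None,
) -> tuple[list[YieldRecord], list[YieldRecord]]:
    """Yields from the stated linear model over features, plus noise.

    yield = beta0 + sum_slot beta_slot * VI_slot
                  + sum_var gamma_var * mean_month(var) + N(0, sigma_y^2),
    floored at ``yield_floor``.  Site records use the same formula on the
    site pixel's features with independent noise; ``site_features`` rows must
    carry unit_id, year, x, y and the 48 feature columns.
    """
    rng = _rng(config, _TAG_YIELD)
    gamma = config.gamma_dict()

    def linear_yield(frame: pd.DataFrame) -> np.ndarray:
        total = np.full(len(frame), config.beta0)
        for k, slot in enumerate(SLOT_NAMES):
            total = total + config.beta_slots[k] * frame[f"VI_{slot}"].to_numpy()
        for var in CLIMATE_VARS:
            mean_var = np.mean([frame[f"{var}_{slot}"].to_numpy() for slot in SLOT_NAMES], axis=0)
            total = total + gamma[var] * mean_var
        return total

    county_records = []
    base = linear_yield(county_features)
    noise = rng.normal(0.0, config.sigma_y, len(base)) if config.sigma_y > 0 else np.zeros(len(base))
    for (_, row), y in zip(county_features.iterrows(), np.maximum(base + noise, config.yield_floor)):
        county_records.append(YieldRecord(int(row["unit_id"]), int(row["year"]), float(y), "county"))

    site_records = []
    if site_features is not None and len(site_features):
        sbase = linear_yield(site_features)
        snoise = (rng.normal(0.0, config.sigma_y, len(sbase))
                  if config.sigma_y > 0 else np.zeros(len(sbase)))
        for (_, row), y in zip(site_features.iterrows(), np.maximum(sbase + snoise, config.yield_floor)):
            site_records.append(
                YieldRecord(int(row["unit_id"]), int(row["year"]), float(y), "site",
                            x=float(row["x"]), y=float(row["y"]))
            )
    return county_records, site_records


# ---------------------------------------------------------------------------
# Whole-scene convenience


def derive_vi_cube(ndvi_cube: RasterCube, vi_name: str) -> RasterCube:
    """Transform an NDVI cube into NDVI, NIRv or kNDVI layers.

    The scene's underlying truth is an NDVI trajectory; a synthetic NIR band
    NIR = 0.25 + 0.35 * NDVI (a smooth increasing canopy brightening) lets
    the same scene express all three indices through the indices module.
    """
    from .indices import compute_kndvi, compute_nirv

    if vi_name == "NDVI":
        return ndvi_cube
    layers = []
    for g in ndvi_cube.layers:
        if vi_name == "kNDVI":
            layers.append(compute_kndvi(g))
        elif vi_name == "NIRv":
            nir = RasterGrid(g.spec, 0.25 + 0.35 * g.values, g.valid.copy())
            layers.append(compute_nirv(g, nir))
        else:
            raise ValueError(f"unknown vi_name {vi_name!r}")
    return RasterCube(ndvi_cube.spec, list(ndvi_cube.timestamps), layers)


@dataclass
class SyntheticScene:
    """A complete generated study: sensors, climate, counties and yields.

    ``truth_monthly`` is the monthly NDVI-truth composite; yields are
    generated from the TRUE (pre-gap, noiseless) features of the configured
    ``target_vi`` (default NIRv), so reconstruction error stays separable
    from model error downstream.  ``fine_obs``/``coarse_obs`` are NDVI
    observations; per-VI observation cubes come from :func:`derive_vi_cube`.
    """

    config: SceneConfig
    counties: CountyMap
    crop_mask: RasterGrid
    climate: ClimateStack
    truth_monthly: dict[int, RasterCube]
    fine_obs: dict[int, RasterCube]
    coarse_obs: dict[int, RasterCube]
    county_features_true: pd.DataFrame
    county_yields: list[YieldRecord]
    site_yields: list[YieldRecord]
    sites: pd.DataFrame  # unit_id, row, col, x, y

    def county_table(self) -> pd.DataFrame:
        """True features joined with generated county yields (model-ready)."""
        ymap = {(r.unit_id, r.year): r.yield_kg_ha for r in self.county_yields}
        fm = self.county_features_true.copy()
        fm["yield_kg_ha"] = [ymap[(int(u), int(y))] for u, y in zip(fm["unit_id"], fm["year"])]
        return fm


def _county_features(
    vi_cubes: dict[int, RasterCube],
    climate: ClimateStack,
    counties: CountyMap,
    crop_mask: RasterGrid,
) -> pd.DataFrame:
    """48-column county-mean feature rows (no target), canonical order."""
    from .features import build_feature_matrix

    # Build with a dummy, strictly positive target then drop it: keeps one
    # code path for the join/ordering logic.
    dummy = [
        YieldRecord(cid, year, 1.0, "county")
        for year in vi_cubes for cid in counties.ids
    ]
    fm = build_feature_matrix(vi_cubes, climate, counties, crop_mask, dummy)
    return fm.drop(columns=["yield_kg_ha"])


def generate_scene(config: SceneConfig, target_vi: str = "NIRv") -> SyntheticScene:
    """Generate the full synthetic study for all seasons in the config."""
    from .reconstruct import monthly_max_composite

    counties, crop_mask = gen_counties(config)
    climate_grids: dict[tuple[int, int], dict[str, RasterGrid]] = {}
    truth_monthly: dict[int, RasterCube] = {}
    fine_obs: dict[int, RasterCube] = {}
    coarse_obs: dict[int, RasterCube] = {}
    for year in config.harvest_years:
        truth = gen_truth_vi(config, year)
        truth_monthly[year] = monthly_max_composite(truth, SeasonSpec(year))
        fine, coarse = gen_observations(truth, config, year)
        fine_obs[year], coarse_obs[year] = fine, coarse
        climate_grids.update(gen_climate(config, year).grids)
    climate = ClimateStack(spec=config.climate_spec, grids=climate_grids)

    target_cubes = {y: derive_vi_cube(c, target_vi) for y, c in truth_monthly.items()}
    county_features = _county_features(target_cubes, climate, counties, crop_mask)
    site_features = _site_features(config, target_cubes, climate, crop_mask)
    county_yields, site_yields = gen_yields(county_features, config, site_features)
    sites = site_features[["unit_id", "row", "col", "x", "y"]].drop_duplicates("unit_id")
    return SyntheticScene(
        config=config,
        counties=counties,
        crop_mask=crop_mask,
        climate=climate,
        truth_monthly=truth_monthly,
        fine_obs=fine_obs,
        coarse_obs=coarse_obs,
        county_features_true=county_features,
        county_yields=county_yields,
        site_yields=site_yields,
        sites=sites,
    )


def _site_features(
    config: SceneConfig,
    truth_monthly: dict[int, RasterCube],
    climate: ClimateStack,
    crop_mask: RasterGrid,
) -> pd.DataFrame:
    """Per-site pixel features for the fixed agro-met site pixels."""
    from .features import pixel_feature_table

    rng = _rng(config, _TAG_COUNTY, 99)
    rr, cc = np.nonzero(crop_mask.valid & (crop_mask.values != 0))
    pick = rng.choice(len(rr), size=min(config.n_sites, len(rr)), replace=False)
    site_rc = set(zip(rr[pick].tolist(), cc[pick].tolist()))
    spec = crop_mask.spec
    frames = []
    for year, cube in truth_monthly.items():
        table = pixel_feature_table(cube, climate, crop_mask, year)
        sel = table[[(r, c) in site_rc for r, c in zip(table["row"], table["col"])]].copy()
        frames.append(sel)
    out = pd.concat(frames, ignore_index=True)
    out["x"] = spec.origin_x + (out["col"] + 0.5) * spec.pixel_width
    out["y"] = spec.origin_y - (out["row"] + 0.5) * spec.pixel_height
    # Stable site ids 1..n in (row, col) order.
    rc_sorted = sorted(site_rc)
    id_map = {rc: i + 1 for i, rc in enumerate(rc_sorted)}
    out["unit_id"] = [id_map[(r, c)] for r, c in zip(out["row"], out["col"])]
    return out
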