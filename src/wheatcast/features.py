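"""County- and pixel-level feature assembly over the wheat mask.

A model row is one (unit, harvest year): 8 monthly slots (Oct..May) times
6 variables (the chosen VI plus Pr, Tmax, Tmin, VPD, SM) = 48 features, with
the statistical yield (kg/ha) as target at county level.  The column layout
is slot-major — ``VI_Oct, Pr_Oct, ..., SM_Oct, VI_Nov, ...`` — and identical
between county and pixel tables, so a county-trained model applies to pixel
rows unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import GridSpec, RasterCube, RasterGrid, resample_bilinear
from .reconstruct import SLOT_NAMES

__all__ = [
    "CLIMATE_VARS",
    "FEATURE_VARS",
    "feature_columns",
    "ClimateStack",
    "CountyMap",
    "YieldRecord",
    "zonal_mean",
    "resample_climate",
    "build_feature_matrix",
    "pixel_feature_table",
    "truncate_to_month",
    "yields_to_frame",
]

logger = logging.getLogger(__name__)

CLIMATE_VARS = ("Pr", "Tmax", "Tmin", "VPD", "SM")
FEATURE_VARS = ("VI",) + CLIMATE_VARS


def feature_columns(last_month: str = "May") -> list[str]:
    """Feature column names in canonical (slot-major) order up to a month."""
    if last_month not in SLOT_NAMES:
        raise ValueError(f"unknown month {last_month!r}; expected one of {SLOT_NAMES}")
    k = SLOT_NAMES.index(last_month) + 1
    return [f"{var}_{slot}" for slot in SLOT_NAMES[:k] for var in FEATURE_VARS]


@dataclass
class ClimateStack:
    """Monthly grids for the five climate variables, keyed by (year, month).

    Units: Pr mm, Tmax/Tmin degC, VPD kPa, SM mm.
    """

    spec: GridSpec
    grids: dict[tuple[int, int], dict[str, RasterGrid]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, slot in self.grids.items():
            missing = set(CLIMATE_VARS) - set(slot)
            if missing:
                raise ValueError(f"climate slot {key} missing variables {sorted(missing)}")
            for g in slot.values():
                if g.spec != self.spec:
                    raise ValueError(f"climate grid at {key} does not share the stack spec")


@dataclass
class CountyMap:
    """County labels on the fine grid: 0 = no county, ids >= 1 named in ``names``."""

    labels: RasterGrid
    names: dict[int, str]

    def __post_init__(self) -> None:
        ids = np.unique(self.labels.values[self.labels.valid].astype(int))
        ids = ids[ids > 0]
        unnamed = [int(i) for i in ids if int(i) not in self.names]
        if unnamed:
            raise ValueError(f"county ids without names: {unnamed}")

    @property
    def ids(self) -> list[int]:
        ids = np.unique(self.labels.values[self.labels.valid].astype(int))
        return [int(i) for i in ids if i > 0]


@dataclass(frozen=True)
class YieldRecord:
    """One observed yield: county statistic or agro-met site measurement."""

    unit_id: int
    year: int
    yield_kg_ha: float
    level: str = "county"  # "county" | "site"
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        if self.yield_kg_ha <= 0:
            raise ValueError("yield must be positive")
        if self.level not in ("county", "site"):
            raise ValueError("level must be 'county' or 'site'")
        if self.level == "site" and (self.x is None or self.y is None):
            raise ValueError("site records need coordinates")


def yields_to_frame(records: Sequence[YieldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"unit_id": r.unit_id, "year": r.year, "yield_kg_ha": r.yield_kg_ha,
             "level": r.level, "x": r.x, "y": r.y}
            for r in records
        ]
    )


def zonal_mean(grid: RasterGrid, counties: CountyMap, crop_mask: RasterGrid) -> dict[int, float]:
    """Arithmetic mean of valid grid values per county over the crop mask.

    Counties with zero contributing pixels are omitted (and logged).
    """
    if grid.spec != counties.labels.spec or grid.spec != crop_mask.spec:
        raise ValueError("grid, counties and crop mask must share a GridSpec")
    keep = (
        grid.valid
        & counties.labels.valid
        & crop_mask.valid
        & (crop_mask.values != 0)
        & (counties.labels.values > 0)
    )
    labels = counties.labels.values.astype(int)[keep]
    vals = grid.values[keep]
    if labels.size == 0:
        return {}
    n = labels.max() + 1
    counts = np.bincount(labels, minlength=n)
    sums = np.bincount(labels, weights=vals, minlength=n)
    out = {}
    for cid in counties.ids:
        if cid < len(counts) and counts[cid] > 0:
            out[cid] = float(sums[cid] / counts[cid])
        else:
            logger.debug("county %d has no contributing pixels; omitted", cid)
    return out


def resample_climate(stack: ClimateStack, target: GridSpec) -> ClimateStack:
    """Bilinearly resample every variable/slot to the target grid."""
    if stack.spec == target:
        return stack
    grids = {
        key: {var: resample_bilinear(g, target) for var, g in slot.items()}
        for key, slot in stack.grids.items()
    }
    return ClimateStack(spec=target, grids=grids)


def _season_slot_keys(harvest_year: int) -> list[tuple[int, int]]:
    return [(harvest_year - 1 if m >= 10 else harvest_year, m) for m in (10, 11, 12, 1, 2, 3, 4, 5)]


def build_feature_matrix(
    vi_cubes: Mapping[int, RasterCube],
    climate: ClimateStack,
    counties: CountyMap,
    crop_mask: RasterGrid,
    yields: Sequence[YieldRecord],
) -> pd.DataFrame:
    """One row per (county, harvest year) with all 48 features and the yield.

    ``vi_cubes`` maps harvest year -> fused 8-slot VI cube on the fine grid.
    Climate is resampled to the fine grid if needed, and both VI and climate
    are averaged over the wheat mask within each county.  Rows missing any
    feature or the yield are dropped and counted in the log.
    """
    climate = resample_climate(climate, crop_mask.spec)
    yframe = yields_to_frame([r for r in yields if r.level == "county"])
    if yframe.empty:
        raise ValueError("no county-level yield records supplied")
    cols = feature_columns()
    rows: list[dict] = []
    dropped = 0
    for year, cube in sorted(vi_cubes.items()):
        slot_keys = _season_slot_keys(year)
        per_county: dict[int, dict[str, float]] = {cid: {} for cid in counties.ids}
        complete = set(counties.ids)
        for k, (slot_name, key) in enumerate(zip(SLOT_NAMES, slot_keys)):
            zm = zonal_mean(cube.layers[k], counties, crop_mask)
            for cid in counties.ids:
                if cid in zm:
                    per_county[cid][f"VI_{slot_name}"] = zm[cid]
                else:
                    complete.discard(cid)
            if key not in climate.grids:
                raise ValueError(f"climate stack lacks slot {key}")
            for var in CLIMATE_VARS:
                zc = zonal_mean(climate.grids[key][var], counties, crop_mask)
                for cid in counties.ids:
                    if cid in zc:
                        per_county[cid][f"{var}_{slot_name}"] = zc[cid]
                    else:
                        complete.discard(cid)
        ymap = {
            (int(r.unit_id), int(r.year)): r.yield_kg_ha
            for r in yields
            if r.level == "county"
        }
        for cid in sorted(counties.ids):
            key = (cid, year)
            if cid not in complete or key not in ymap:
                dropped += 1
                continue
            row = {"unit_id": cid, "year": year}
            row.update({c: per_county[cid][c] for c in cols})
            row["yield_kg_ha"] = ymap[key]
            rows.append(row)
    if not rows:
        raise ValueError("no complete (county, year) rows after joining features and yields")
    if dropped:
        logger.info("dropped %d (county, year) rows lacking features or yield", dropped)
    return pd.DataFrame(rows, columns=["unit_id", "year", *cols, "yield_kg_ha"])


def pixel_feature_table(
    vi_cube: RasterCube,
    climate: ClimateStack,
    crop_mask: RasterGrid,
    year: int,
) -> pd.DataFrame:
    """Per-pixel feature rows for one season, same 48-column layout as county rows.

    Only crop-mask pixels whose VI series is gap-free are emitted; each row
    carries its (row, col) pixel index so predictions can be written back to
    a map.
    """
    if vi_cube.spec != crop_mask.spec:
        raise ValueError("VI cube and crop mask must share a GridSpec")
    climate = resample_climate(climate, crop_mask.spec)
    mask = crop_mask.valid & (crop_mask.values != 0)
    vi_ok = vi_cube.valid_array().all(axis=0)
    keep = mask & vi_ok
    rr, cc = np.nonzero(keep)
    if rr.size == 0:
        raise ValueError("no crop pixels with complete VI series")
    cols = feature_columns()
    data = {"row": rr, "col": cc}
    slot_keys = _season_slot_keys(year)
    vi_vals = vi_cube.values_array()
    for k, (slot_name, key) in enumerate(zip(SLOT_NAMES, slot_keys)):
        data[f"VI_{slot_name}"] = vi_vals[k][rr, cc]
        for var in CLIMATE_VARS:
            data[f"{var}_{slot_name}"] = climate.grids[key][var].values[rr, cc]
    frame = pd.DataFrame(data)
    frame["unit_id"] = frame["row"] * crop_mask.spec.n_cols + frame["col"]
    frame["year"] = year
    return frame[["unit_id", "year", "row", "col", *cols]]


def truncate_to_month(fm: pd.DataFrame, last_month: str) -> pd.DataFrame:
    """Drop feature columns for slots after ``last_month`` (season order).

    Metadata and target columns are untouched; used for forward-month
    (in-season) prediction experiments.
    """
    keep_features = set(feature_columns(last_month))
    all_features = set(feature_columns())
    cols = [c for c in fm.columns if c not in all_features or c in keep_features]
    return fm[cols].copy()
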