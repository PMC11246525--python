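"""Evaluation battery: metrics, leave-one-year-out, RE maps, yield mapping.

R² is the coefficient of determination 1 - SS_res/SS_tot (about the observed
mean; may be negative out of sample), RMSE is in kg/ha, and RE is the signed
relative error 100·(pred - obs)/obs in percent.  Relative errors are banded
at ±20% — the threshold used to call obvious over-/under-estimation — with
the inner band closed: [-20, 20].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import CountyMap, YieldRecord, zonal_mean
from .models import (
    META_COLUMNS,
    TARGET_COLUMN,
    FittedModel,
    ModelSpec,
    predict,
    random_split,
    tenfold_cv_select,
    train,
)
from .raster import GridSpec, RasterGrid
from .reconstruct import SLOT_NAMES

__all__ = [
    "EvalReport",
    "LoyoResult",
    "metrics",
    "leave_one_year_out",
    "re_by_unit",
    "yield_map",
    "validate_map",
    "forward_month_analysis",
]

logger = logging.getLogger(__name__)

RE_BANDS = ("<-20%", "-20..20%", ">20%")


@dataclass
class EvalReport:
    """R², RMSE and per-record relative errors for one comparison."""

    r2: float
    rmse: float
    n: int
    records: pd.DataFrame  # columns: unit_id, year, observed, predicted, re_percent
    r2_defined: bool = True


@dataclass
class LoyoResult:
    """Per-year evaluation reports from leave-one-year-out validation."""

    reports: dict[int, EvalReport] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.reports)

    def pooled_records(self) -> pd.DataFrame:
        return pd.concat([r.records for r in self.reports.values()], ignore_index=True)


def metrics(
    observed: Sequence[float],
    predicted: Sequence[float],
    unit_ids: Sequence | None = None,
    years: Sequence | None = None,
) -> EvalReport:
    """RMSE, coefficient of determination, and per-record relative errors."""
    obs = np.asarray(observed, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 records")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        r2, r2_defined = np.nan, False
        logger.warning("observed values have zero variance; R^2 undefined")
    else:
        r2, r2_defined = 1.0 - float(np.sum((pred - obs) ** 2)) / ss_tot, True
    with np.errstate(divide="ignore", invalid="ignore"):
        re = 100.0 * (pred - obs) / obs
    records = pd.DataFrame(
        {
            "unit_id": unit_ids if unit_ids is not None else np.arange(n),
            "year": years if years is not None else np.zeros(n, dtype=int),
            "observed": obs,
            "predicted": pred,
            "re_percent": re,
        }
    )
    return EvalReport(r2=float(r2), rmse=rmse, n=int(n), records=records, r2_defined=r2_defined)


def leave_one_year_out(fm: pd.DataFrame, spec: ModelSpec) -> LoyoResult:
    """Hold out each harvest year in turn: train on the rest, score the year.

    Years with fewer than 2 rows are skipped (and logged); the union of test
    sets over retained years is exactly the retained rows.
    """
    years = sorted(fm["year"].unique())
    if len(years) < 3:
        raise ValueError("need at least 3 distinct years")
    result = LoyoResult()
    for y in years:
        test = fm[fm["year"] == y]
        if len(test) < 2:
            logger.warning("year %s has %d row(s); skipped in LOYO", y, len(test))
            continue
        model = train(fm[fm["year"] != y], spec)
        pred = predict(model, test)
        result.reports[int(y)] = metrics(
            test[TARGET_COLUMN].to_numpy(), pred,
            unit_ids=test["unit_id"].to_numpy(), years=test["year"].to_numpy(),
        )
    return result


def re_by_unit(loyo: LoyoResult) -> pd.DataFrame:
    """Flat (unit, year, RE%) table with ±20% error bands for mapping."""
    if not loyo.reports:
        raise ValueError("empty LOYO result")
    table = loyo.pooled_records()[["unit_id", "year", "re_percent"]].copy()
    re = table["re_percent"].to_numpy()
    band = np.where(re < -20.0, RE_BANDS[0], np.where(re > 20.0, RE_BANDS[2], RE_BANDS[1]))
    table["band"] = band
    return table


def yield_map(model: FittedModel, pixel_fm: pd.DataFrame, spec: GridSpec) -> RasterGrid:
    """Predict per-pixel yields and write them back to a map.

    Non-crop pixels are invalid; negative predictions are clipped to 0 and
    counted in the log (yields are physical quantities).
    """
    pred = predict(model, pixel_fm)
    n_neg = int((pred < 0).sum())
    if n_neg:
        logger.info("clipped %d negative pixel predictions to 0", n_neg)
    pred = np.clip(pred, 0.0, None)
    values = np.zeros(spec.shape)
    valid = np.zeros(spec.shape, bool)
    rr = pixel_fm["row"].to_numpy(int)
    cc = pixel_fm["col"].to_numpy(int)
    values[rr, cc] = pred
    valid[rr, cc] = True
    return RasterGrid(spec, values, valid)


def validate_map(
    ymap: RasterGrid,
    counties: CountyMap,
    crop_mask: RasterGrid,
    county_yields: Sequence[YieldRecord],
    site_yields: Sequence[YieldRecord],
) -> tuple[EvalReport, EvalReport]:
    """Score a pixel yield map against county statistics and site records.

    County check: crop-masked zonal mean of the map vs the statistical yield.
    Site check: the map pixel containing each site's coordinates vs the
    observed site yield; sites outside the grid or on invalid pixels are
    skipped and logged.
    """
    zm = zonal_mean(ymap, counties, crop_mask)
    c_obs, c_pred, c_ids, c_years = [], [], [], []
    for rec in county_yields:
        if rec.level == "county" and rec.unit_id in zm:
            c_obs.append(rec.yield_kg_ha)
            c_pred.append(zm[rec.unit_id])
            c_ids.append(rec.unit_id)
            c_years.append(rec.year)
    s_obs, s_pred, s_ids, s_years = [], [], [], []
    for rec in site_yields:
        if rec.level != "site":
            continue
        try:
            row, col = ymap.spec.point_to_rowcol(rec.x, rec.y)
        except ValueError:
            logger.warning("site %s at (%s, %s) outside grid; skipped", rec.unit_id, rec.x, rec.y)
            continue
        if not ymap.valid[row, col]:
            logger.warning("site %s falls on an invalid map pixel; skipped", rec.unit_id)
            continue
        s_obs.append(rec.yield_kg_ha)
        s_pred.append(float(ymap.values[row, col]))
        s_ids.append(rec.unit_id)
        s_years.append(rec.year)
    county_report = metrics(c_obs, c_pred, c_ids, c_years)
    site_report = metrics(s_obs, s_pred, s_ids, s_years)
    return county_report, site_report


def forward_month_analysis(
    fm: pd.DataFrame,
    algorithm: str,
    grid: Sequence[dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """In-season prediction skill as a function of the last month observed.

    For each last month Oct..May the features are truncated, hyperparameters
    re-selected by ten-fold CV on the 70/30 training portion, and the model
    scored on the held-out 30% (the same split for every month, so the curve
    is paired).  Returns 8 rows (last_month, n_features, r2, rmse) in season
    order; the May row equals the standard full-feature evaluation.
    """
    from .features import truncate_to_month  # local import to avoid cycle

    rows = []
    train_fm, test_fm = random_split(fm, seed=seed)
    for month in SLOT_NAMES:
        tr = truncate_to_month(train_fm, month)
        te = truncate_to_month(test_fm, month)
        spec = tenfold_cv_select(tr, algorithm, grid=grid, seed=seed)
        model = train(tr, spec)
        report = metrics(te[TARGET_COLUMN].to_numpy(), predict(model, te))
        n_features = len([c for c in tr.columns if c not in META_COLUMNS])
        rows.append({"last_month": month, "n_features": n_features,
                     "r2": report.r2, "rmse": report.rmse})
    return pd.DataFrame(rows)
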