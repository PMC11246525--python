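# Methods

## Problem and pipeline

Winter wheat in a double-cropping system is sown in late September/early
October and harvested in late May; its canopy development over the 8 months
October→May, as seen by a vegetation index (VI), carries most of the
information about the eventual yield. The package predicts county yields
(kg/ha) from monthly VI plus five monthly climate covariates —
precipitation Pr (mm), maximum/minimum temperature Tmax/Tmin (°C), vapour
pressure deficit VPD (kPa), soil moisture SM (mm) — and then applies the
county-trained model per pixel to map yield at the fine-sensor resolution.

The pipeline has five stages, each a module:

1. **raster** — grid/cube data model, single-band GeoTIFF I/O (via
   tifffile, writing the standard pixel-scale/tiepoint/nodata tags),
   bilinear resampling, mask application.
2. **indices** — NDVI = (NIR−RED)/(NIR+RED) clipped to [−1, 1];
   NIRv = (NDVI−0.08)·NIR; kNDVI = tanh(NDVI²). Cloud screening enters
   purely as per-date validity masks.
3. **reconstruct** — per season: monthly maximum-value composites of the
   cloud-masked fine sensor; the coarse sensor cloud-masked, temporally
   interpolated, composited, Savitzky–Golay smoothed, and bilinearly
   resampled to the fine grid; fine gaps filled by plain substitution of
   the resampled coarse value (no inter-sensor bias correction); residual
   gaps linearly interpolated in slot index; a final SG pass over the fused
   series. The result is gap-free wherever at least one source slot was
   valid; dead pixels are dropped and counted.
4. **features** — county means of VI and climate over the wheat mask
   (both are masked before averaging), one row per (county, harvest year):
   48 features in fixed slot-major order, ``VI_Oct, Pr_Oct, … SM_May``.
   The per-pixel table uses the byte-identical schema so a county-trained
   model transfers unchanged.
5. **models / evaluate** — LightGBM on the flat vector; an LSTM on the
   8-step sequence of 6 monthly channels. Protocol: 70/30 random row
   split; ten-fold CV on the training portion selects hyperparameters from
   a small grid (ties break by grid order); the winner refits on the full
   training portion and is scored on the held-out 30% with
   R² = 1 − SS_res/SS_tot (negative out of sample is possible and kept)
   and RMSE in kg/ha. Leave-one-year-out retrains with each harvest year
   held out in turn. Relative error 100·(pred−obs)/obs is banded at ±20%
   with the inner band closed. Pixel maps clip negative predictions to 0
   (counted, never silent); county map validation uses the crop-masked
   zonal mean, site validation the map pixel containing the site
   coordinates (pixel-center containment, no footprint model).

## Key parameters

| parameter | default | why |
|---|---|---|
| SG window / order | 5 / 2 | largest odd window leaving ≥3 interior positions on an 8-point series; quadratic preserves a single seasonal peak |
| monthly slots | Oct..May, nominal day 15 | interpolation is in slot index; day-level timing on a monthly grid would be spurious precision |
| coarse factor k | 16 | ≈ 30 m vs 500 m sensor footprint ratio |
| fine / coarse revisit | 2 / 4 obs·month⁻¹ | ≈ 16-day vs 8-day revisit |
| cloud fraction | 0.30 | winter-season cloud gaps large enough to force the fusion path |
| LSTM | 1 layer, hidden 32–64, Adam 0.01, batch 32, ≤200 epochs, early stop patience 20 on a 10% holdout, +1 forget-gate bias | an 8-step sequence needs little capacity; grid kept small for desk-scale CV |
| LGBM grid | lr ∈ {0.05, 0.1}, leaves ∈ {15, 31}, ≤500 trees | standard small-data ranges |
| standardization | z-score per column, training stats only (target too, for the LSTM) | leakage control; matrices stay interpretable |

Edge handling in SG smoothing fits the polynomial to the first/last full
window and evaluates it at the edge positions (scipy's ``mode="interp"``),
so any global polynomial of degree ≤ order is reproduced exactly everywhere
— the property the tests pin down, together with the window-5/order-2
impulse center response 17/35 derived from the normal equations.

Bilinear resampling uses pixel-center coordinates (row 0 at top, half-open
pixel extents) and is conservative about validity: a target cell is invalid
if any source neighbour *with nonzero weight* is invalid, or if the target
center falls outside the source pixel-center hull. Ignoring zero-weight
neighbours makes resampling onto the same grid an exact identity while
still refusing to interpolate across data holes; gap repair is the
reconstruction stage's job, not the resampler's.

## The synthetic study

No public archive provides the satellite/climate/yearbook inputs, so the
``synthdata`` module generates a study with the same statistical structure;
everything is a pure function of a ``SceneConfig`` (including its seed).

* **Truth**: per pixel, a double-logistic VI trajectory (base 0.15, peak
  0.75, green-up mid-January, senescence in May, peak in April). Three
  variance components drive yield-relevant variation: a scalar per-year
  amplitude anomaly (sd 0.15 — good vs bad years, shared across the scene),
  a static smooth spatial productivity field (sd 0.10, correlation length
  15 px), and independent smooth monthly anomaly fields (sd 0.05). The
  monthly anomalies are what make month-resolved information identifiable
  (the timing experiments rest on them); the shared amplitude components
  reproduce the strong cross-month correlation real VI series show.
* **Sensors**: the fine sensor samples the truth 2×/month with N(0, 0.02)
  noise and spatially correlated cloud gaps (thresholded smoothed noise,
  exactly the configured fraction per date); the coarse sensor is the k×k
  block mean of the truth 4×/month plus noise, gap-free, with edge blocks
  averaging over the grid intersection.
* **Counties & mask**: a near-equal rectangular tiling (100 counties by
  default) and a clumped 60% crop mask; every county keeps ≥1 crop pixel.
* **Climate**: five variables on a coarser grid (with a one-pixel margin so
  resampling covers the tile), each = monthly climatology + planar gradient
  + scalar year anomaly + smooth spatial noise; Tmax = Tmin + a positive
  gap by construction.
* **Yields**: county yield = β₀ + Σ_slot β_slot·VI_slot + Σ_var γ_var·
  (season-mean of var) + N(0, σ_y²), floored at 100 kg/ha; site yields use
  the same formula on the site pixel's features with independent noise, at
  13 fixed crop pixels. Yields are generated from the *true* (pre-gap,
  noiseless) features of the configured target VI (NIRv by default), so
  reconstruction error stays separable from model error. β magnitudes are
  set for the NIRv scale such that default county yields land at mean
  ≈ 5900, sd ≈ 1400 kg/ha — the 4000–8000 kg/ha regime of county wheat
  statistics — against the default yield noise σ_y = 300 kg/ha. The default
  scene is 100 counties × 20 seasons = 2000 county-year records.

What the generator does **not** emulate: directional/atmospheric
reflectance effects, inter-sensor calibration bias (fusion substitutes
coarse values unadjusted, so any real bias would propagate), real phenology
variation (sowing-date shifts, frost damage), irregular county geometry,
and nonlinear or threshold yield responses. Passing tests therefore show
that the pipeline's mechanics are correct and that the protocol recovers a
known signal under realistic gap/noise structure — not that the printed
skill transfers to any particular real region. An optional "rainfed
corner" flag is deliberately absent; spatially uneven bias appears in the
leave-one-year-out RE maps only to the extent the model under-fits.

## Design choices where the design was open

* Maximum-value compositing operates on the VI (computed per observation
  date, then composited), not on reflectance bands.
* One shared SG parameter set for the coarse-series pass and the final
  fused pass.
* The 70/30 split is by county-year row, not grouped by county or year;
  grouping is available in the leave-one-year-out analysis, which is
  precisely the grouped-by-year protocol. The ungrouped random split
  measures interpolation skill, and the gap between the two (0.92 vs 0.81
  mean R² in the worked example) quantifies the year-leakage effect.
* CV folds are ungrouped for the same reason; hyperparameter selection runs
  on the 70% training portion only.
* Forward-month analysis retrains per truncation (Oct..last month) rather
  than masking inputs of a full-season model, with the same split per
  month so the curve is paired.
* County validation of yield maps uses the simple crop-pixel mean (no area
  weighting), matching how the features were aggregated.

## Problem sizes

The default test run keeps every experiment at desk scale as a package
choice: module tests use 1–6×6 grids with hand-computable answers; the
integration scene is 48×48 / 9 counties / 4 seasons; the recovery checks
run the full 120×120 / 100 counties / 20 seasons scene; the timing-curve
and map-consistency experiments use reduced scenes (96×96 / 36 counties /
8 seasons and 48×48 / 16 counties / 4 seasons) over 5 seeds each.
`scripts/acceptance.py` runs the full study scale end to end (~4 minutes,
one CPU).

## Known limitations

* Plain coarse-for-fine substitution ignores inter-sensor bias; a bias
  correction (e.g. per-pixel regression between overlapping dates) would be
  the first accuracy improvement on real data.
* The NumPy LSTM is exact but unaccelerated; at much larger sample sizes a
  framework implementation would be preferable.
* Bilinear resampling refuses the first/last half coarse pixel at the tile
  edge (outside the pixel-center hull); edge pixels there rely on the fine
  sensor alone and are dropped if it never sees them.
* R² is undefined for zero-variance observations and flagged, not faked.
* No uncertainty quantification: predictions are point estimates.
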