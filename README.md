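# wheatcast

County- and pixel-level winter-wheat yield prediction from fused
fine/coarse-resolution vegetation-index time series and monthly climate.

Fine-resolution optical sensors (Landsat-class: ~30 m, 16-day revisit) see
too few cloud-free scenes over a winter-wheat season to support yield
modelling, while coarse sensors (MODIS-class: ~500 m, 8-day revisit) see
often but too coarsely. `wheatcast` implements the standard remedy as a
tested pipeline: reconstruct a gap-free monthly VI series at the fine grid
by substituting bilinearly-resampled coarse observations into fine-sensor
cloud gaps, aggregate VI and climate over a wheat mask to county means,
train sequence (LSTM) and gradient-boosting (LightGBM) regressors against
county yield statistics, and evaluate with random-split, leave-one-year-out,
relative-error, pixel-mapping and in-season-timing analyses. It is aimed at
agricultural remote-sensing researchers who want the whole chain — including
a synthetic-data generator that stands in for the satellite, climate and
yearbook inputs, so every stage is testable without downloads.

## The model

Vegetation indices from red/NIR surface reflectance:

    NDVI  = (NIR − RED) / (NIR + RED)
    NIRv  = (NDVI − 0.08) · NIR
    kNDVI = tanh(NDVI²)

Reconstruction, per season (October → May, 8 monthly slots):

1. cloud-mask both sensors; maximum-value composite each calendar month;
2. temporally interpolate and Savitzky–Golay smooth (window 5, order 2) the
   coarse series; resample it bilinearly to the fine grid;
3. fill fine-sensor gaps with the resampled coarse value, interpolate any
   remainder in time, and SG-smooth the fused series.

A model row is one (county, harvest year): 8 slots × (VI, Pr, Tmax, Tmin,
VPD, SM) = 48 features, county-averaged over the wheat mask, with the
statistical yield (kg/ha) as target. Rows are split 70/30 at random;
ten-fold cross-validation on the training portion selects hyperparameters;
R² (= 1 − SS_res/SS_tot) and RMSE score the held-out portion. The LSTM
consumes the features as an 8-step sequence of 6 monthly channels; LightGBM
consumes the flat vector. A county-trained model applies unchanged to
per-pixel feature rows, which is how the 30 m yield maps are produced.

## Worked example

The numbered drivers under `analysis/` run the study on a moderate
synthetic scene (64 counties × 10 seasons, 96×96 grid, 30% cloud gaps):

```bash
python analysis/01_simulate_scene.py     # generate the synthetic study
python analysis/02_reconstruct_fusion.py # fine/coarse fusion + gap stats
python analysis/03_build_features.py     # county feature matrix
python analysis/04_compare_models.py     # 3 VIs x 2 algorithms
python analysis/05_leave_one_year_out.py
python analysis/06_yield_maps.py
python analysis/07_prediction_timing.py
```

`04_compare_models.py` prints, for example:

```
vi_name algorithm       r2       rmse  n_test
   NDVI      lstm 0.915162 364.320379     192
   NDVI      lgbm 0.909020 377.276535     192
   NIRv      lstm 0.916889 360.592918     192
   NIRv      lgbm 0.908714 377.910783     192
  kNDVI      lstm 0.909469 376.345253     192
  kNDVI      lgbm 0.908033 379.317934     192

best cell: NIRv + LSTM (R2 = 0.917, RMSE = 361 kg/ha on 192 held-out rows)
```

i.e. the NIRv + LSTM combination wins the paired comparison (the synthetic
yields are generated from NIRv features, so this ordering is the correct
recovery). `05` then shows that forecasting a truly unseen year is harder
than the random split (mean leave-one-year-out R² 0.806 vs 0.917), because
the shared year-level growing conditions can no longer leak into training;
`06` shows county-level map validation beating site-level (R² 0.929 vs
0.900 — aggregation averages out pixel-scale error); and `07` shows the
in-season skill curve flattening by spring, when most of the season's
information is on the table before harvest.

Results land under `results/analysis/` as CSV (plus GeoTIFF maps).

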