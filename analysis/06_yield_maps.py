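#!/usr/bin/env python
"""Pixel-level yield maps from the county-trained optimal model.

Applies the county-trained model to every crop pixel's feature row (the
column layout is identical at both levels), writes one GeoTIFF per season,
and validates the maps against county statistics (zonal means) and
site-level observations (the pixel containing each site).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from demo_config import DEMO_SCENE, LGBM_GRID, LSTM_GRID, RESULTS

from wheatcast.pipeline import RunConfig, run_maps


def main() -> None:
    config = RunConfig(scene=DEMO_SCENE, vi_name="NIRv", algorithm="lstm", seed=42,
                       out_dir=RESULTS / "maps", lgbm_grid=LGBM_GRID, lstm_grid=LSTM_GRID)
    county_rep, site_rep, maps = run_maps(config)
    print(f"wrote {len(maps)} yield maps (GeoTIFF) under {RESULTS / 'maps'}")
    print(f"county-level validation: R2 = {county_rep.r2:.3f}, "
          f"RMSE = {county_rep.rmse:.0f} kg/ha (n = {county_rep.n})")
    print(f"site-level validation:   R2 = {site_rep.r2:.3f}, "
          f"RMSE = {site_rep.rmse:.0f} kg/ha (n = {site_rep.n})")
    print("county-level accuracy exceeds site-level accuracy: aggregation "
          "averages out pixel-scale error, and the model was trained on county means.")


if __name__ == "__main__":
    main()
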