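#!/usr/bin/env python
"""Leave-one-year-out validation of the optimal model.

Each season serves once as the test set while all other seasons train the
model — the honest test of forecasting an unseen year, where the shared
year-level growing conditions cannot leak into training.  Also bands each
county-year relative error at +/-20%.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from demo_config import DEMO_SCENE, LGBM_GRID, LSTM_GRID, RESULTS

import numpy as np

from wheatcast.pipeline import RunConfig, run_loyo


def main() -> None:
    config = RunConfig(scene=DEMO_SCENE, vi_name="NIRv", algorithm="lstm", seed=42,
                       out_dir=RESULTS / "loyo", lgbm_grid=LGBM_GRID, lstm_grid=LSTM_GRID)
    loyo, bands = run_loyo(config)
    for year in loyo.years:
        r = loyo.reports[year]
        print(f"  {year}: R2 = {r.r2:6.3f}  RMSE = {r.rmse:7.1f} kg/ha  (n = {r.n})")
    r2s = [loyo.reports[y].r2 for y in loyo.years]
    print(f"\nacross years: mean R2 {np.mean(r2s):.3f}, range "
          f"[{np.min(r2s):.3f}, {np.max(r2s):.3f}]")
    shares = bands.band.value_counts(normalize=True)
    print("relative-error bands:",
          ", ".join(f"{b}: {shares.get(b, 0.0):.1%}" for b in ("<-20%", "-20..20%", ">20%")))
    print(f"wrote loyo_by_year.csv and re_bands.csv under {RESULTS / 'loyo'}")


if __name__ == "__main__":
    main()
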