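#!/usr/bin/env python
"""Generate the synthetic study and summarize what it contains.

Emulates the data situation of a county-level winter-wheat yield study: a
sparse, cloud-gapped fine sensor and a dense coarse sensor observing a
seasonal VI truth, monthly climate fields, a county partition with a crop
mask, and county/site yields from a known linear model plus noise.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from demo_config import DEMO_SCENE, RESULTS

import numpy as np

from wheatcast.features import yields_to_frame
from wheatcast.synthdata import generate_scene


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    scene = generate_scene(DEMO_SCENE)
    cfg = scene.config

    fm = scene.county_table()
    y = fm["yield_kg_ha"]
    print(f"scene: {cfg.n_rows}x{cfg.n_cols} fine grid, coarse factor {cfg.coarse_factor}, "
          f"{cfg.n_counties} counties, {cfg.n_years} seasons "
          f"({cfg.first_harvest_year}-{cfg.harvest_years[-1]})")
    print(f"county-year records: {len(fm)}; site records: {len(scene.site_yields)} "
          f"at {len(scene.sites)} sites")
    print(f"county yields: mean {y.mean():.0f} kg/ha, sd {y.std():.0f}, "
          f"range [{y.min():.0f}, {y.max():.0f}]")

    gap = 1.0 - np.mean([c.valid_array().mean() for c in scene.fine_obs.values()])
    print(f"fine-sensor cloud gap fraction: {gap:.2f} "
          f"(configured {cfg.cloud_fraction:.2f})")

    yields_to_frame(scene.county_yields).to_csv(RESULTS / "county_yields.csv", index=False)
    yields_to_frame(scene.site_yields).to_csv(RESULTS / "site_yields.csv", index=False)
    print(f"wrote county_yields.csv and site_yields.csv under {RESULTS}")


if __name__ == "__main__":
    main()
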