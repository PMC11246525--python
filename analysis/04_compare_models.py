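#!/usr/bin/env python
"""Compare yield models: {NDVI, NIRv, kNDVI} x {LSTM, LGBM}.

Every cell is hyperparameter-selected by ten-fold CV on the training portion
of one shared 70/30 split, so the comparison is paired.  The best cell is
the study's 'optimal model' used by the later drivers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from demo_config import DEMO_SCENE, LGBM_GRID, LSTM_GRID, RESULTS

from wheatcast.pipeline import RunConfig, run_compare


def main() -> None:
    config = RunConfig(scene=DEMO_SCENE, seed=42, out_dir=RESULTS / "compare",
                       lgbm_grid=LGBM_GRID, lstm_grid=LSTM_GRID)
    table = run_compare(config)
    print(table.to_string(index=False))
    best = table.loc[table.r2.idxmax()]
    print(f"\nbest cell: {best.vi_name} + {best.algorithm.upper()} "
          f"(R2 = {best.r2:.3f}, RMSE = {best.rmse:.0f} kg/ha on {best.n_test} held-out rows)")
    print(f"wrote compare.csv under {RESULTS / 'compare'}")


if __name__ == "__main__":
    main()
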