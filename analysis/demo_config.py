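"""Shared settings for the numbered analysis drivers.

A moderate scene (64 counties x 10 seasons on a 96 x 96 grid) keeps every
driver under a couple of minutes on one CPU while preserving the study's
structure; scripts/acceptance.py runs the full 100 x 20 study scale.
"""

from pathlib import Path

from wheatcast.synthdata import SceneConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

DEMO_SCENE = SceneConfig(
    n_rows=96, n_cols=96, n_counties=64, n_years=10,
    coarse_factor=16, climate_factor=32, seed=42,
)

LGBM_GRID = [
    {"learning_rate": 0.05, "num_leaves": 31, "n_estimators": 300},
    {"learning_rate": 0.1, "num_leaves": 31, "n_estimators": 300},
]
LSTM_GRID = [{"hidden_size": 64}]
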