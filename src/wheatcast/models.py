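"""Yield regressors: LightGBM benchmark and LSTM, with the split/CV protocol.

Protocol: rows are randomly split 70/30 into training and validation;
ten-fold cross-validation *on the training portion* selects hyperparameters
from a small grid; the selected model is refit on the full training portion
and scored on the held-out 30%.  Features are z-scored per column (and the
target for the LSTM) using training statistics only.

The LGBM consumes the flat 48-column matrix; the LSTM consumes the same
features reshaped to an 8-step (or truncated-length) sequence of the 6
per-month channels in season order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .features import FEATURE_VARS, feature_columns
from .lstm import LSTMRegressor
from .reconstruct import SLOT_NAMES

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "ModelSpec",
    "FittedModel",
    "random_split",
    "tenfold_cv_select",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("lstm", "lgbm")
TARGET_COLUMN = "yield_kg_ha"
META_COLUMNS = ("unit_id", "year", "row", "col", TARGET_COLUMN)

#: Small default hyperparameter grids (kept desk-scale on purpose).
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "lgbm": [
        {"learning_rate": lr, "num_leaves": nl}
        for lr in (0.05, 0.1)
        for nl in (15, 31)
    ],
    "lstm": [{"hidden_size": h} for h in (32, 64)],
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")

    @classmethod
    def make(cls, algorithm: str, hyperparameters: dict | None = None, seed: int = 0,
             standardize: bool = True) -> "ModelSpec":
        hp = tuple(sorted((hyperparameters or {}).items()))
        return cls(algorithm, hp, seed, standardize)

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)


@dataclass
class FittedModel:
    """A trained regressor bound to its feature schema and scaling stats."""

    spec: ModelSpec
    schema: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    state: object = field(repr=False, default=None)


def _feature_cols(fm: pd.DataFrame) -> list[str]:
    return [c for c in fm.columns if c not in META_COLUMNS]


def _design(fm: pd.DataFrame, schema: Sequence[str]) -> np.ndarray:
    cols = _feature_cols(fm)
    if cols != list(schema):
        raise ValueError("feature matrix does not match the model's training schema")
    X = fm[list(schema)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _to_sequence(X: np.ndarray, schema: Sequence[str]) -> np.ndarray:
    """Reshape flat slot-major features to (N, n_slots, 6) in season order."""
    n_vars = len(FEATURE_VARS)
    if len(schema) % n_vars:
        raise ValueError("schema is not a whole number of monthly slots")
    n_slots = len(schema) // n_vars
    expected = feature_columns(SLOT_NAMES[n_slots - 1])
    if list(schema) != expected:
        raise ValueError("schema is not in canonical slot-major order")
    return X.reshape(X.shape[0], n_slots, n_vars)


def random_split(
    fm: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible disjoint 70/30 row split (train size = round(f * n))."""
    n = len(fm)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return fm.iloc[perm[:n_train]].copy(), fm.iloc[perm[n_train:]].copy()


def tenfold_indices(fm: pd.DataFrame, seed: int = 0, n_folds: int = 10):
    """The shuffled near-equal fold partition used by ten-fold selection."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    return list(kf.split(fm))


def tenfold_cv_select(
    fm: pd.DataFrame,
    algorithm: str,
    grid: Sequence[dict] | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> ModelSpec:
    """Pick the grid entry with lowest mean held-out RMSE over ten folds.

    Folds are near-equal disjoint row partitions; ties break by grid order.
    """
    grid = list(DEFAULT_GRIDS[algorithm] if grid is None else grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return ModelSpec.make(algorithm, grid[0], seed=seed)
    if len(fm) < 20:
        raise ValueError("need at least 20 rows for ten-fold selection")
    folds = tenfold_indices(fm, seed=seed, n_folds=n_folds)
    scores = []
    for hp in grid:
        spec = ModelSpec.make(algorithm, hp, seed=seed)
        fold_rmse = []
        for tr_idx, te_idx in folds:
            model = train(fm.iloc[tr_idx], spec)
            pred = predict(model, fm.iloc[te_idx])
            obs = fm.iloc[te_idx][TARGET_COLUMN].to_numpy()
            fold_rmse.append(float(np.sqrt(np.mean((pred - obs) ** 2))))
        scores.append(float(np.mean(fold_rmse)))
    best = int(np.argmin(scores))
    logger.info("CV(%s): mean fold RMSE per grid entry %s -> entry %d", algorithm, scores, best)
    return ModelSpec.make(algorithm, grid[best], seed=seed)


def train(fm: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit the specified regressor on a feature matrix with targets."""
    if TARGET_COLUMN not in fm.columns:
        raise ValueError("feature matrix lacks the target column")
    schema = _feature_cols(fm)
    X = _design(fm, schema)
    y = fm[TARGET_COLUMN].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target values")

    if spec.standardize:
        x_mean = X.mean(axis=0)
        x_std = X.std(axis=0)
        x_std[x_std == 0] = 1.0
    else:
        x_mean = np.zeros(X.shape[1])
        x_std = np.ones(X.shape[1])
    Xs = (X - x_mean) / x_std

    if spec.algorithm == "lgbm":
        hp = {"learning_rate": 0.1, "num_leaves": 31, "n_estimators": 500, **spec.hp}
        model = lgb.LGBMRegressor(
            **hp,
            random_state=spec.seed % (2**31),
            verbosity=-1,
            deterministic=True,
            force_row_wise=True,
        )
        model.fit(pd.DataFrame(Xs, columns=schema), y)
        return FittedModel(spec, schema, x_mean, x_std, 0.0, 1.0, state=model)

    # LSTM: standardize the target too, reshape to monthly sequences.
    y_mean = float(y.mean())
    y_std = float(y.std()) or 1.0
    ys = (y - y_mean) / y_std
    seq = _to_sequence(Xs, schema)
    hp = {"hidden_size": 64, **spec.hp}
    model = LSTMRegressor(seed=spec.seed, **hp)
    model.fit(seq, ys)
    return FittedModel(spec, schema, x_mean, x_std, y_mean, y_std, state=model)


def predict(model: FittedModel, fm: pd.DataFrame) -> np.ndarray:
    """Predicted yield (kg/ha), one finite value per row."""
    X = _design(fm, model.schema)
    Xs = (X - model.x_mean) / model.x_std
    if model.spec.algorithm == "lgbm":
        pred = model.state.predict(pd.DataFrame(Xs, columns=model.schema))
    else:
        seq = _to_sequence(Xs, model.schema)
        pred = model.state.predict(seq) * model.y_std + model.y_mean
    pred = np.asarray(pred, dtype=np.float64)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("model produced non-finite predictions")
    return pred
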