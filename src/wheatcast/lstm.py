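"""A compact NumPy LSTM regressor for short monthly feature sequences.

One recurrent layer over an 8-step (or shorter, for in-season truncations)
sequence of 6 channels, followed by a linear head on the final hidden state.
Trained with Adam on mean-squared error, mini-batches, and early stopping on
a held-out fraction of the training rows.  Gates are computed in the usual
i/f/g/o order with a +1 forget-gate bias at initialization; gradients are
exact backpropagation-through-time (verified against finite differences in
the test suite).

Sequences this short need very little capacity, so hidden sizes of 32-64
and a few hundred epochs are ample; all randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMRegressor"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def init_params(n_channels: int, hidden: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    sw = np.sqrt(6.0 / (n_channels + 4 * hidden))
    su = np.sqrt(6.0 / (hidden + 4 * hidden))
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias
    return {
        "W": rng.uniform(-sw, sw, (n_channels, 4 * hidden)),
        "U": rng.uniform(-su, su, (hidden, 4 * hidden)),
        "b": b,
        "w_out": rng.normal(0.0, 1.0 / np.sqrt(hidden), hidden),
        "b_out": np.zeros(1),
    }


def forward(params: dict[str, np.ndarray], X: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run the LSTM over X (N, T, D); return predictions (N,) and caches."""
    N, T, _ = X.shape
    H = params["w_out"].shape[0]
    h = np.zeros((N, H))
    c = np.zeros((N, H))
    cache = {"i": [], "f": [], "g": [], "o": [], "c": [], "tc": [], "h_prev": [], "c_prev": []}
    for t in range(T):
        a = X[:, t, :] @ params["W"] + h @ params["U"] + params["b"]
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        cache["h_prev"].append(h)
        cache["c_prev"].append(c)
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        for k, v in zip(("i", "f", "g", "o", "c", "tc"), (i, f, g, o, c, tc)):
            cache[k].append(v)
    cache["h_last"] = h
    pred = h @ params["w_out"] + params["b_out"][0]
    return pred, cache


def loss_and_grads(
    params: dict[str, np.ndarray], X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean-squared-error loss and exact BPTT gradients."""
    N, T, _ = X.shape
    H = params["w_out"].shape[0]
    pred, cache = forward(params, X)
    resid = pred - y
    loss = float(np.mean(resid**2))

    dpred = 2.0 * resid / N
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["w_out"] = cache["h_last"].T @ dpred
    grads["b_out"] = np.array([dpred.sum()])
    dh = np.outer(dpred, params["w_out"])
    dc = np.zeros((N, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
        tc = cache["tc"][t]
        c_prev = cache["c_prev"][t]
        h_prev = cache["h_prev"][t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
        )
        grads["W"] += X[:, t, :].T @ da
        grads["U"] += h_prev.T @ da
        grads["b"] += da.sum(axis=0)
        dh = da @ params["U"].T
        dc = dc * f
    return loss, grads


@dataclass
class LSTMRegressor:
    """Sequence regressor: X of shape (N, T, D) -> scalar target.

    Inputs and targets are assumed pre-standardized by the caller; the model
    itself applies no scaling.
    """

    hidden_size: int = 64
    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    params_: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        N, T, D = X.shape
        rng = np.random.default_rng(self.seed)
        params = init_params(D, self.hidden_size, rng)

        n_val = max(1, int(round(self.val_fraction * N))) if N >= 20 else 0
        perm = rng.permutation(N)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = {k: p.copy() for k, p in params.items()}
        bad_epochs = 0
        n_tr = len(Xtr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, self.batch_size):
                idx = order[start : start + self.batch_size]
                _, grads = loss_and_grads(params, Xtr[idx], ytr[idx])
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    params[k] = params[k] - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if n_val:
                val_pred, _ = forward(params, Xval)
                val_loss = float(np.mean((val_pred - yval) ** 2))
            else:
                tr_pred, _ = forward(params, Xtr)
                val_loss = float(np.mean((tr_pred - ytr) ** 2))
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_params = {k: p.copy() for k, p in params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        self.params_ = best_params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        pred, _ = forward(self.params_, np.asarray(X, dtype=np.float64))
        return pred
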