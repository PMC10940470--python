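"""Minimal 1-D convolutional network on NumPy.

Architecture (all convolutions zero-padded to "same" length, width-3
kernels): conv(16, ReLU) -> max-pool(2) -> conv(32, ReLU) -> global average
pool -> dense(32, ReLU) -> dense(2, softmax).  Trained by mini-batch SGD
with momentum on a weighted cross-entropy loss; per-sample weights enter the
gradient as multipliers, which is what lets the network act as a boosting
base learner.

Everything is deterministic given the RNG passed in: parameter
initialization and epoch shuffling are the only stochastic steps.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNConfig", "CNNEstimator"]


@dataclass
class CNNConfig:
    """Boosted-CNN hyperparameters.

    ``n_estimators``/``epochs``/``learning_rate`` default to the published
    operating point (100 rounds, 10 epochs, shrinkage 0.1).  ``learning_rate``
    is the boosting shrinkage; ``sgd_lr`` is the optimizer step size, a
    separate knob.
    """

    n_estimators: int = 100
    epochs: int = 10
    learning_rate: float = 0.1
    batch_size: int = 32
    sgd_lr: float = 0.05
    momentum: float = 0.9
    conv_channels: tuple[int, int] = (16, 32)
    kernel_size: int = 3
    dense_units: int = 32

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1-D convolution.  X: (B,T,C), W: (O,C,K) -> (B,T,O)."""
    K = W.shape[2]
    pl, pr = (K - 1) // 2, K // 2
    Xp = np.pad(X, ((0, 0), (pl, pr), (0, 0)))
    win = sliding_window_view(Xp, K, axis=1)  # (B, T, C, K)
    Z = np.einsum("btck,ock->bto", win, W, optimize=True) + b
    return Z, win


def _conv_backward(dZ, win, W, T, C):
    """Gradients for the same-padded conv. Returns (dX, dW, db)."""
    K = W.shape[2]
    pl = (K - 1) // 2
    dW = np.einsum("bto,btck->ock", dZ, win, optimize=True)
    db = dZ.sum(axis=(0, 1))
    dwin = np.einsum("bto,ock->btck", dZ, W, optimize=True)
    B = dZ.shape[0]
    dXp = np.zeros((B, T + K - 1, C))
    for k in range(K):
        dXp[:, k : k + T, :] += dwin[:, :, :, k]
    return dXp[:, pl : pl + T, :], dW, db


class CNNEstimator:
    """One trainable CNN base learner.

    Parameters live in ``self.params`` (a dict of arrays); ``clone`` deep
    copies them, which is how boosting rounds inherit the previous round's
    weights (transfer learning).
    """

    def __init__(self, input_dim: int, config: CNNConfig | None = None):
        if input_dim < 2:
            raise ValueError("input_dim must be >= 2")
        self.input_dim = int(input_dim)
        self.config = config or CNNConfig()
        self.params: dict[str, np.ndarray] = {}
        self.epochs_run = 0

    # -- initialization ----------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> "CNNEstimator":
        cfg = self.config
        c1, c2 = cfg.conv_channels
        k = cfg.kernel_size
        h = cfg.dense_units

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": he((c1, 1, k), k),
            "b1": np.zeros(c1),
            "W2": he((c2, c1, k), c1 * k),
            "b2": np.zeros(c2),
            "Wd": he((c2, h), c2),
            "bd": np.zeros(h),
            "Wo": he((h, 2), h),
            "bo": np.zeros(2),
        }
        return self

    def clone(self) -> "CNNEstimator":
        new = CNNEstimator(self.input_dim, self.config)
        new.params = copy.deepcopy(self.params)
        new.epochs_run = self.epochs_run
        return new

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray, cache: bool = False):
        P = self.params
        X0 = X[:, :, None]
        Z1, win1 = _conv_forward(X0, P["W1"], P["b1"])
        A1 = np.maximum(Z1, 0.0)

        T1 = A1.shape[1]
        L2 = T1 // 2
        if L2 >= 1:
            Ae = A1[:, : 2 * L2].reshape(X.shape[0], L2, 2, -1)
            Pool = Ae.max(axis=2)
            pidx = Ae.argmax(axis=2)
        else:
            Pool, pidx, Ae = A1, None, None

        Z2, win2 = _conv_forward(Pool, P["W2"], P["b2"])
        A2 = np.maximum(Z2, 0.0)
        G = A2.mean(axis=1)  # global average pool
        Zd = G @ P["Wd"] + P["bd"]
        H = np.maximum(Zd, 0.0)
        logits = H @ P["Wo"] + P["bo"]
        probs = _softmax(logits)
        if not cache:
            return probs
        return probs, dict(
            X0=X0, Z1=Z1, A1=A1, win1=win1, L2=L2, pidx=pidx,
            Pool=Pool, Z2=Z2, A2=A2, win2=win2, G=G, Zd=Zd, H=H,
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"feature width {X.shape[1]} != training width {self.input_dim}"
            )
        return self._forward(X)

    # -- backward ----------------------------------------------------------
    def _gradients(self, X, y01, w):
        P = self.params
        B = X.shape[0]
        probs, c = self._forward(X, cache=True)
        Y1h = np.zeros((B, 2))
        Y1h[np.arange(B), y01] = 1.0
        wn = w / w.sum()
        dlogits = (probs - Y1h) * wn[:, None]

        g = {}
        g["Wo"] = c["H"].T @ dlogits
        g["bo"] = dlogits.sum(0)
        dH = dlogits @ P["Wo"].T
        dZd = dH * (c["Zd"] > 0)
        g["Wd"] = c["G"].T @ dZd
        g["bd"] = dZd.sum(0)
        dG = dZd @ P["Wd"].T

        T2 = c["A2"].shape[1]
        dA2 = np.repeat(dG[:, None, :] / T2, T2, axis=1)
        dZ2 = dA2 * (c["Z2"] > 0)
        dPool, g["W2"], g["b2"] = _conv_backward(
            dZ2, c["win2"], P["W2"], c["Pool"].shape[1], c["Pool"].shape[2]
        )

        if c["pidx"] is not None:
            L2 = c["L2"]
            dAe = np.zeros((B, L2, 2, c["A1"].shape[2]))
            np.put_along_axis(
                dAe, c["pidx"][:, :, None, :], dPool[:, :, None, :], axis=2
            )
            dA1 = np.zeros_like(c["A1"])
            dA1[:, : 2 * L2] = dAe.reshape(B, 2 * L2, -1)
        else:
            dA1 = dPool
        dZ1 = dA1 * (c["Z1"] > 0)
        _, g["W1"], g["b1"] = _conv_backward(
            dZ1, c["win1"], P["W1"], self.input_dim, 1
        )

        loss = float(-(wn * np.log(probs[np.arange(B), y01] + 1e-300)).sum())
        return g, loss

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray | None = None,
        epochs: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> "CNNEstimator":
        """Continue training from the current parameters.

        ``sample_weight`` multiplies each sample's cross-entropy term; it is
        renormalized within each mini-batch.
        """
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        p = len(X)
        if sample_weight is None:
            sample_weight = np.full(p, 1.0 / p)
        sample_weight = np.asarray(sample_weight, dtype=float)
        if rng is None:
            rng = np.random.default_rng(0)
        if not self.params:
            self.init_params(rng)
        epochs = cfg.epochs if epochs is None else epochs

        vel = {k: np.zeros_like(v) for k, v in self.params.items()}
        bs = min(cfg.batch_size, p)
        self.loss_history: list[float] = getattr(self, "loss_history", [])
        for _ in range(epochs):
            order = rng.permutation(p)
            ep_loss = 0.0
            for s in range(0, p, bs):
                idx = order[s : s + bs]
                g, loss = self._gradients(X[idx], y[idx], sample_weight[idx])
                ep_loss += loss * len(idx)
                for k in self.params:
                    vel[k] = cfg.momentum * vel[k] - cfg.sgd_lr * g[k]
                    self.params[k] += vel[k]
            self.loss_history.append(ep_loss / p)
            self.epochs_run += 1
        return self
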