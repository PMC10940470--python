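"""Gradient-boosted tree head and convex score fusion.

The tree head is LightGBM (gradient-based one-side sampling + exclusive
feature bundling); its internals are the published algorithm and are used
as-is rather than re-derived.  The final association probability of a pair
is the convex fusion ``P = alpha * C + (1 - alpha) * F`` of the boosted-CNN
score ``C`` and the tree score ``F`` (default alpha = 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from ._cnn import CNNConfig
from .adaboost_cnn import BoostedCNNModel, boosted_cnn_scores, train_boosted_cnn
from .data_io import LabeledDataset

__all__ = [
    "GBMParams",
    "EnsembleModel",
    "train_gbm",
    "fuse_scores",
    "train_ensemble",
    "ensemble_scores",
]


@dataclass
class GBMParams:
    """Tree-head hyperparameters (defaults: 100 estimators, shrinkage 0.1)."""

    n_estimators: int = 100
    learning_rate: float = 0.1
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _as_frame(X: np.ndarray) -> pd.DataFrame:
    """Stable column names so fit- and predict-time schemas agree."""
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def train_gbm(
    ds: LabeledDataset, params: GBMParams | None = None, seed: int = 0
) -> LGBMClassifier:
    """Fit the LightGBM head on a labeled pair dataset.

    Single-threaded deterministic mode so identical seeds give identical
    models.  ``params.extra`` passes keys straight through (useful to drop
    the minimum-leaf guards on tiny toy sets).
    """
    params = params or GBMParams()
    y = np.asarray(ds.y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = LGBMClassifier(
        n_estimators=params.n_estimators,
        learning_rate=params.learning_rate,
        random_state=int(seed) % (2**31),
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
        **params.extra,
    )
    clf.fit(_as_frame(ds.X), y)
    return clf


def fuse_scores(
    c_scores: np.ndarray, f_scores: np.ndarray, alpha: float = 0.4
) -> np.ndarray:
    """Convex fusion ``alpha * c + (1 - alpha) * f`` of two score vectors.

    Both inputs must be probabilities in [0, 1] and of equal length;
    ``alpha`` in [0, 1].  The endpoints reproduce the single heads exactly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    c = np.asarray(c_scores, dtype=float)
    f = np.asarray(f_scores, dtype=float)
    if c.shape != f.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {f.shape}")
    for name, v in (("c_scores", c), ("f_scores", f)):
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError(f"{name} outside [0, 1]")
    return np.clip(alpha * c + (1.0 - alpha) * f, 0.0, 1.0)


@dataclass
class EnsembleModel:
    """Trained boosted-CNN head + tree head + fusion weight.

    ``beta`` is always ``1 - alpha``.  When built by the evaluation pipeline
    the featurizer used in training is attached so unseen pairs can be
    scored by (row, col) index.
    """

    boosted_cnn: BoostedCNNModel
    gbm: LGBMClassifier
    alpha: float
    featurizer: Any = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha

    def component_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c, _ = boosted_cnn_scores(self.boosted_cnn, X)
        f = self.gbm.predict_proba(_as_frame(X))[:, 1]
        return c, f

    def predict(self, X: np.ndarray) -> np.ndarray:
        c, f = self.component_scores(X)
        return fuse_scores(c, f, self.alpha)


def ensemble_scores(
    model: EnsembleModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (cnn_scores, gbm_scores, fused_scores) for a feature matrix."""
    c, f = model.component_scores(X)
    return c, f, fuse_scores(c, f, model.alpha)


def train_ensemble(
    ds: LabeledDataset,
    cnn_cfg: CNNConfig | None = None,
    gbm_cfg: GBMParams | None = None,
    alpha: float = 0.4,
    seed: int = 0,
) -> EnsembleModel:
    """Train both heads on the same dataset with seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(2)
    cnn_seed = int(ss[0].generate_state(1)[0] % (2**31))
    gbm_seed = int(ss[1].generate_state(1)[0] % (2**31))
    cfg = cnn_cfg or CNNConfig()
    cnn = train_boosted_cnn(
        ds,
        Q=cfg.n_estimators,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        seed=cnn_seed,
        config=cfg,
    )
    gbm = train_gbm(ds, gbm_cfg, seed=gbm_seed)
    return EnsembleModel(boosted_cnn=cnn, gbm=gbm, alpha=alpha)
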