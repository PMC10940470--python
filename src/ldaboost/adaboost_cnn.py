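"""Real-AdaBoost (SAMME.R) ensemble of CNN base learners with transfer learning.

Boosting maintains a probability vector ``D`` over the training pairs.  Each
round fits a small 1-D CNN on the weighted data, then reweights: samples the
round's CNN gets wrong gain mass, samples it gets right lose mass, and ``D``
is renormalized to sum 1.  Instead of re-initializing every round, round
``q+1``'s network starts from round ``q``'s trained parameters, so later
rounds fine-tune on the hard examples rather than learning from scratch.

Prediction aggregates per-round class probabilities on the log-odds scale:
each estimator contributes ``c_k = log o_k - (1/K) * sum_k' log o_k'`` and
the ensemble takes the argmax of the summed contributions (a softmax over
the sums gives a continuous association score).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._cnn import CNNConfig, CNNEstimator
from .data_io import LabeledDataset

__all__ = [
    "CNNConfig",
    "BoostedCNNModel",
    "init_sample_weights",
    "train_boosted_cnn",
    "fit_single_cnn",
    "aggregate_probas",
    "boosted_cnn_scores",
]

_PROB_FLOOR = 1e-12


def init_sample_weights(p: int) -> np.ndarray:
    """Uniform initial boosting weights: a length-``p`` vector of ``1/p``."""
    if p <= 0:
        raise ValueError("p must be a positive integer")
    return np.full(p, 1.0 / p)


@dataclass
class BoostedCNNModel:
    """Ordered list of trained CNN estimators plus boosting bookkeeping."""

    estimators: list[CNNEstimator]
    learning_rate: float
    sample_weights: np.ndarray  # D after the final round
    weight_history: list[float] = field(default_factory=list)  # sum(D) checks
    round_errors: list[float] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.estimators)

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Save as a directory of parameter arrays plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = self.estimators[0].config
        manifest = {
            "n_rounds": self.n_rounds,
            "learning_rate": self.learning_rate,
            "input_dim": self.estimators[0].input_dim,
            "config": {
                "conv_channels": list(cfg.conv_channels),
                "kernel_size": cfg.kernel_size,
                "dense_units": cfg.dense_units,
                "batch_size": cfg.batch_size,
                "sgd_lr": cfg.sgd_lr,
                "momentum": cfg.momentum,
            },
            "round_errors": self.round_errors,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.save(directory / "sample_weights.npy", self.sample_weights)
        for q, est in enumerate(self.estimators):
            for name, arr in est.params.items():
                np.save(directory / f"est{q:04d}_{name}.npy", arr)

    @classmethod
    def load(cls, directory: str | Path) -> "BoostedCNNModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        c = manifest["config"]
        cfg = CNNConfig(
            conv_channels=tuple(c["conv_channels"]),
            kernel_size=c["kernel_size"],
            dense_units=c["dense_units"],
            batch_size=c["batch_size"],
            sgd_lr=c["sgd_lr"],
            momentum=c["momentum"],
        )
        estimators = []
        for q in range(manifest["n_rounds"]):
            est = CNNEstimator(manifest["input_dim"], cfg)
            est.params = {
                name: np.load(directory / f"est{q:04d}_{name}.npy")
                for name in ("W1", "b1", "W2", "b2", "Wd", "bd", "Wo", "bo")
            }
            estimators.append(est)
        return cls(
            estimators=estimators,
            learning_rate=manifest["learning_rate"],
            sample_weights=np.load(directory / "sample_weights.npy"),
            round_errors=manifest["round_errors"],
        )


def _samme_r_update(
    D: np.ndarray, probs: np.ndarray, y01: np.ndarray, learning_rate: float
) -> np.ndarray:
    """One SAMME.R weight update (K = 2), followed by renormalization.

    ``D_i <- D_i * exp(-lr * ((K-1)/K) * y~_i . log p_i)`` with the coding
    ``y~ = +1`` on the true class and ``-1/(K-1)`` elsewhere.
    """
    p = np.clip(probs, _PROB_FLOOR, 1.0)
    logp = np.log(p)
    coding = np.full_like(p, -1.0)  # -1/(K-1) with K=2
    coding[np.arange(len(y01)), y01] = 1.0
    exponent = -learning_rate * 0.5 * (coding * logp).sum(axis=1)
    D = D * np.exp(exponent)
    total = D.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("degenerate boosting weights")
    return D / total


def fit_single_cnn(
    ds: LabeledDataset,
    epochs: int = 10,
    seed: int = 0,
    config: CNNConfig | None = None,
    sample_weight: np.ndarray | None = None,
) -> CNNEstimator:
    """Train one standalone CNN (the Q = 1 boosting round, no reweighting)."""
    cfg = config or CNNConfig()
    rng = np.random.default_rng(seed)
    est = CNNEstimator(ds.d, cfg).init_params(rng)
    w = sample_weight if sample_weight is not None else init_sample_weights(ds.p)
    est.fit(ds.X, ds.y, sample_weight=w, epochs=epochs, rng=rng)
    return est


def train_boosted_cnn(
    ds: LabeledDataset,
    Q: int = 100,
    epochs: int = 10,
    learning_rate: float = 0.1,
    seed: int = 0,
    config: CNNConfig | None = None,
) -> BoostedCNNModel:
    """Train ``Q`` CNN rounds under SAMME.R boosting with transfer learning.

    Parameters
    ----------
    ds : LabeledDataset
        Pair features and binary labels; both classes must be present.
    Q, epochs, learning_rate : int, int, float
        Boosting rounds, SGD epochs per round, and boosting shrinkage.
        Published operating point: 100 / 10 / 0.1.
    seed : int
        Sole source of randomness (round-1 parameter init, minibatch order).
    config : CNNConfig, optional
        Architecture and optimizer settings; ``Q``/``epochs``/
        ``learning_rate`` given here override the config's values.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = np.asarray(ds.X, dtype=float)
    y = np.asarray(ds.y).astype(int)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    cfg = config or CNNConfig()
    rng = np.random.default_rng(seed)
    D = init_sample_weights(ds.p)
    estimators: list[CNNEstimator] = []
    weight_sums: list[float] = []
    round_errors: list[float] = []

    est = CNNEstimator(ds.d, cfg).init_params(rng)
    for q in range(Q):
        if q > 0:
            est = estimators[-1].clone()  # transfer: warm-start from round q-1
        est.fit(X, y, sample_weight=D, epochs=epochs, rng=rng)
        probs = est.predict_proba(X)
        pred = (probs[:, 1] > probs[:, 0]).astype(int)
        round_errors.append(float(np.sum(D * (pred != y))))
        D = _samme_r_update(D, probs, y, learning_rate)
        s = float(D.sum())
        assert abs(s - 1.0) < 1e-9, "boosting weights must sum to 1"
        weight_sums.append(s)
        estimators.append(est)

    return BoostedCNNModel(
        estimators=estimators,
        learning_rate=learning_rate,
        sample_weights=D,
        weight_history=weight_sums,
        round_errors=round_errors,
    )


def aggregate_probas(probas: list[np.ndarray]) -> np.ndarray:
    """Sum per-estimator log-odds contributions ``c_k`` over rounds.

    Each (p, 2) probability array contributes
    ``c_k = log o_k - (1/2)(log o_1 + log o_2)`` per sample (probabilities
    floored at 1e-12 before the logs); uniform output (0.5, 0.5) contributes
    exactly zero.  Returns the (p, 2) summed contributions.
    """
    if not probas:
        raise ValueError("need at least one estimator output")
    agg = np.zeros_like(np.asarray(probas[0], dtype=float))
    for o in probas:
        logp = np.log(np.clip(o, _PROB_FLOOR, 1.0))
        agg += logp - logp.mean(axis=1, keepdims=True)
    return agg


def boosted_cnn_scores(
    model: BoostedCNNModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous class-1 (association) scores and hard labels.

    The hard label is the argmax of the summed contributions, with exact
    ties resolved to non-association (the conservative call for candidate
    nomination); the score is the softmax of the two sums, class-1 entry.
    """
    X = np.asarray(X, dtype=float)
    agg = aggregate_probas([est.predict_proba(X) for est in model.estimators])
    hard = (agg[:, 1] > agg[:, 0]).astype(int)
    shifted = agg - agg.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    scores = e[:, 1] / e.sum(axis=1)
    return scores, hard
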