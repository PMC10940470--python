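"""Cold-start cross-validation, metrics, ablation, and candidate ranking.

Three fivefold schemes are supported: holding out lncRNAs (``lncrna``,
every pair of a held-out lncRNA is unseen), holding out diseases
(``disease``), and holding out sampled pairs (``pair``).  Performance is
summarized by precision, recall, accuracy, F1 (at a fixed score threshold),
AUC and AUPR, reported per fold and as mean +/- sd.  Candidate discovery
ranks the unobserved lncRNAs of a disease by fused association score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import average_precision_score, roc_auc_score

from ._cnn import CNNConfig
from .adaboost_cnn import boosted_cnn_scores, train_boosted_cnn
from .data_io import AssociationMatrix, LabeledDataset
from .gbm_ensemble import (
    EnsembleModel,
    GBMParams,
    _as_frame,
    fuse_scores,
    train_ensemble,
    train_gbm,
)
from .svd_features import PairFeaturizer, svd_factorize

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "CVResult",
    "PipelineConfig",
    "RankedCandidates",
    "make_folds",
    "compute_metrics",
    "cross_validate",
    "ablation_sweep",
    "rank_candidates",
    "train_full_model",
]

logger = logging.getLogger("ldaboost")

METRIC_NAMES = ("precision", "recall", "accuracy", "f1", "auc", "aupr")
DEFAULT_ALPHA_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    ``e`` is the SVD truncation rank (pair feature width is ``2e``; the
    default e = 32 gives d = 64).  ``mask`` controls whether each fold's
    held-out positives are zeroed before factorization (leakage-free; set
    False for the literal variant that factorizes the full matrix).
    """

    e: int = 32
    scaling: str = "sqrt_sigma"
    mask: bool = True
    sampling_mode: str = "balanced"
    neg_ratio: float = 1.0
    cnn: CNNConfig = field(default_factory=CNNConfig)
    gbm: GBMParams = field(default_factory=GBMParams)
    alpha: float = 0.4
    threshold: float = 0.5
    seed: int = 0


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from nested config-file keys.

    Recognized layout::

        alpha: 0.4
        seed: 0
        cnn: {Q: 100, epochs: 10, learning_rate: 0.1, batch_size: 32}
        gbm: {n_estimators: 100, learning_rate: 0.1}
        features: {e: 32, scaling: sqrt_sigma, mask_mode: true}
        sampling: {mode: balanced, neg_ratio: 1.0}
    """
    cnn_d = dict(d.get("cnn", {}))
    if "Q" in cnn_d:
        cnn_d["n_estimators"] = cnn_d.pop("Q")
    gbm_d = dict(d.get("gbm", {}))
    feats = d.get("features", {})
    sampling = d.get("sampling", {})
    return PipelineConfig(
        e=feats.get("e", 32),
        scaling=feats.get("scaling", "sqrt_sigma"),
        mask=bool(feats.get("mask_mode", True)),
        sampling_mode=sampling.get("mode", "balanced"),
        neg_ratio=sampling.get("neg_ratio", 1.0),
        cnn=CNNConfig(**cnn_d),
        gbm=GBMParams(**gbm_d),
        alpha=d.get("alpha", 0.4),
        threshold=d.get("threshold", 0.5),
        seed=d.get("seed", 0),
    )


@dataclass
class FoldPlan:
    """K disjoint held-out index sets covering the entities (or pairs)."""

    mode: str
    k: int
    folds: list[np.ndarray]
    seed: int
    pairs: np.ndarray | None = None  # (p, 2) sampled pairs, pair mode only


@dataclass
class MetricsReport:
    """The six evaluation metrics at one operating point."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float
    aupr: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class CVResult:
    """Per-fold reports plus mean +/- sd aggregates."""

    reports: list[MetricsReport]
    fold_ids: list[int]
    mean: dict[str, float]
    sd: dict[str, float]
    skipped: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"fold": fid, **rep.as_dict()}
            for fid, rep in zip(self.fold_ids, self.reports)
        ]
        return pd.DataFrame(rows)


def make_folds(
    am: AssociationMatrix,
    mode: str,
    k: int = 5,
    seed: int = 0,
    neg_ratio: float = 1.0,
) -> FoldPlan:
    """Partition lncRNAs, diseases, or sampled pairs into ``k`` folds.

    Entity modes partition the entity index set; a fold's test side is every
    pair touching a held-out entity.  Pair mode first draws a balanced pair
    sample (all positives plus ``neg_ratio`` negatives per positive) and
    partitions it directly.  Fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if mode == "lncrna":
        count = am.n
    elif mode == "disease":
        count = am.m
    elif mode == "pair":
        pos = am.positive_pairs()
        zeros = am.negative_pairs()
        n_neg = int(np.floor(neg_ratio * len(pos)))
        if n_neg > len(zeros):
            raise ValueError("not enough zero cells for requested neg_ratio")
        idx = rng.choice(len(zeros), size=n_neg, replace=False)
        pairs = np.vstack([pos, zeros[idx]])
        pairs = pairs[rng.permutation(len(pairs))]
        if k > len(pairs):
            raise ValueError(f"k={k} exceeds {len(pairs)} sampled pairs")
        folds = [f.copy() for f in np.array_split(rng.permutation(len(pairs)), k)]
        return FoldPlan(mode=mode, k=k, folds=folds, seed=seed, pairs=pairs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if k > count:
        raise ValueError(f"k={k} exceeds {count} {mode} entities")
    folds = [f.copy() for f in np.array_split(rng.permutation(count), k)]
    return FoldPlan(mode=mode, k=k, folds=folds, seed=seed)


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Confusion-matrix metrics at ``score >= threshold`` plus AUC and AUPR.

    AUC is the probability that a random positive outscores a random
    negative (ties count 1/2); AUPR uses the step-interpolation rule.  With
    a single-class ``y_true`` the ranking metrics are NaN (with a warning)
    while the thresholded metrics are still returned.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = float(np.mean(pred == y))
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    if len(np.unique(y)) < 2:
        logger.warning("single-class labels: AUC/AUPR undefined, returning NaN")
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))
    return MetricsReport(
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        auc=auc,
        aupr=aupr,
        threshold=threshold,
    )


def _fold_seed(seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % 2**31)


def _prepare_fold(
    am: AssociationMatrix, config: PipelineConfig, plan: FoldPlan, fold_idx: int
):
    """Build one fold's train/test feature matrices and labels.

    Returns None when the fold cannot be evaluated (no test positives or no
    test negatives).  Test negatives are drawn from the test side only, with
    a fold-specific seed.
    """
    Y = am.Y
    rng = np.random.default_rng(_fold_seed(config.seed, 7, fold_idx))

    if plan.mode == "pair":
        test_idx = plan.folds[fold_idx]
        train_idx = np.setdiff1d(np.arange(len(plan.pairs)), test_idx)
        test_pairs = plan.pairs[test_idx]
        train_pairs = plan.pairs[train_idx]
    else:
        held = np.asarray(plan.folds[fold_idx])
        axis = 0 if plan.mode == "lncrna" else 1
        in_test = np.isin(np.arange(Y.shape[axis]), held)
        cell_in_test = in_test[:, None] if axis == 0 else in_test[None, :]
        cell_in_test = np.broadcast_to(cell_in_test, Y.shape)

        test_pos = np.argwhere((Y == 1) & cell_in_test)
        test_zero = np.argwhere((Y == 0) & cell_in_test)
        train_pos = np.argwhere((Y == 1) & ~cell_in_test)
        train_zero = np.argwhere((Y == 0) & ~cell_in_test)
        if len(test_pos) == 0 or len(test_zero) == 0 or len(train_pos) == 0:
            return None

        n_neg_test = min(
            int(np.floor(config.neg_ratio * len(test_pos))), len(test_zero)
        )
        if n_neg_test == 0:
            return None
        test_neg = test_zero[rng.choice(len(test_zero), n_neg_test, replace=False)]
        test_pairs = np.vstack([test_pos, test_neg])

        if config.sampling_mode == "all_pairs":
            train_pairs = np.vstack([train_pos, train_zero])
        else:
            n_neg_train = min(
                int(np.floor(config.neg_ratio * len(train_pos))), len(train_zero)
            )
            train_neg = train_zero[
                rng.choice(len(train_zero), n_neg_train, replace=False)
            ]
            train_pairs = np.vstack([train_pos, train_neg])
        train_pairs = train_pairs[rng.permutation(len(train_pairs))]

    y_train = Y[train_pairs[:, 0], train_pairs[:, 1]].astype(int)
    y_test = Y[test_pairs[:, 0], test_pairs[:, 1]].astype(int)
    if y_test.sum() == 0 or y_test.sum() == len(y_test) or len(np.unique(y_train)) < 2:
        return None

    # factorize with held-out positives zeroed (no leakage) unless disabled
    if config.mask:
        Y_fit = Y.astype(float).copy()
        pos_mask = y_test == 1
        Y_fit[test_pairs[pos_mask, 0], test_pairs[pos_mask, 1]] = 0.0
        if not Y_fit.any():
            return None
    else:
        Y_fit = Y.astype(float)

    fact = svd_factorize(Y_fit, e=config.e)
    featurizer = PairFeaturizer(fact, scaling=config.scaling)
    X_train = featurizer.pair_matrix(train_pairs)
    X_test = featurizer.pair_matrix(test_pairs)
    return X_train, y_train, X_test, y_test


def _aggregate(reports: list[MetricsReport], fold_ids, skipped) -> CVResult:
    mean, sd = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        mean[name] = float(np.mean(vals)) if len(vals) else float("nan")
        sd[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return CVResult(
        reports=reports, fold_ids=fold_ids, mean=mean, sd=sd, skipped=skipped
    )


def cross_validate(
    am: AssociationMatrix, config: PipelineConfig, plan: FoldPlan
) -> CVResult:
    """Run the full pipeline over a fold plan and aggregate the metrics.

    Per fold: refit the truncated SVD on the training-side matrix, assemble
    balanced train/test pair sets, train the fused ensemble, score the test
    pairs.  Folds whose test side lacks positives (or negatives) are skipped
    with a warning and excluded from the aggregate.
    """
    reports: list[MetricsReport] = []
    fold_ids: list[int] = []
    skipped: list[int] = []
    for fold_idx in range(plan.k):
        prepared = _prepare_fold(am, config, plan, fold_idx)
        if prepared is None:
            logger.warning("fold %d skipped (degenerate test side)", fold_idx)
            skipped.append(fold_idx)
            continue
        X_train, y_train, X_test, y_test = prepared
        ds = LabeledDataset(
            X=X_train,
            y=y_train,
            pairs=np.column_stack(
                [np.arange(len(y_train)), np.zeros(len(y_train), int)]
            ),
        )
        model = train_ensemble(
            ds,
            cnn_cfg=config.cnn,
            gbm_cfg=config.gbm,
            alpha=config.alpha,
            seed=_fold_seed(config.seed, 11, fold_idx),
        )
        fused = model.predict(X_test)
        rep = compute_metrics(y_test, fused, threshold=config.threshold)
        logger.info(
            "fold %d/%d: auc=%.4f aupr=%.4f", fold_idx + 1, plan.k, rep.auc, rep.aupr
        )
        reports.append(rep)
        fold_ids.append(fold_idx)
    return _aggregate(reports, fold_ids, skipped)


def ablation_sweep(
    am: AssociationMatrix,
    config: PipelineConfig,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    variants: Sequence[str] = ("ensemble", "adaboost_cnn", "adaboost", "lightgbm"),
    plan: FoldPlan | None = None,
) -> pd.DataFrame:
    """Fusion-weight sweep and boosting-variant comparison on shared folds.

    All variants see identical folds, features and seeds; the heads are
    trained once per fold and every (variant, alpha) row is derived from the
    cached head scores, so ``alpha = 0`` reproduces the tree head and
    ``alpha = 1`` the boosted CNN exactly.  The plain-AdaBoost variant uses
    depth-1 decision stumps on the same features.
    """
    if any(a < 0 or a > 1 for a in alphas):
        raise ValueError("alphas must lie in [0, 1]")
    if plan is None:
        plan = make_folds(am, "pair", k=5, seed=config.seed, neg_ratio=config.neg_ratio)

    per_fold: dict[tuple[str, float | None], list[MetricsReport]] = {}
    for fold_idx in range(plan.k):
        prepared = _prepare_fold(am, config, plan, fold_idx)
        if prepared is None:
            logger.warning("fold %d skipped in ablation", fold_idx)
            continue
        X_train, y_train, X_test, y_test = prepared
        ds = LabeledDataset.from_arrays(X_train, y_train)
        seed = _fold_seed(config.seed, 11, fold_idx)
        cfg = config.cnn
        cnn = train_boosted_cnn(
            ds,
            Q=cfg.n_estimators,
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            seed=seed,
            config=cfg,
        )
        gbm = train_gbm(ds, config.gbm, seed=seed)
        ada = AdaBoostClassifier(
            n_estimators=config.gbm.n_estimators,
            learning_rate=config.gbm.learning_rate,
            random_state=seed,
        ).fit(X_train, y_train)

        c, _ = boosted_cnn_scores(cnn, X_test)
        f = gbm.predict_proba(_as_frame(X_test))[:, 1]
        a = ada.predict_proba(X_test)[:, 1]

        scored: list[tuple[str, float | None, np.ndarray]] = [
            ("adaboost_cnn", None, c),
            ("lightgbm", None, f),
            ("adaboost", None, a),
        ]
        scored.extend(
            ("ensemble", alpha, fuse_scores(c, f, alpha)) for alpha in alphas
        )
        for variant, alpha, s in scored:
            if variant not in variants:
                continue
            per_fold.setdefault((variant, alpha), []).append(
                compute_metrics(y_test, s, threshold=config.threshold)
            )

    rows = []
    for (variant, alpha), reps in per_fold.items():
        agg = _aggregate(reps, list(range(len(reps))), [])
        row = {"variant": variant, "alpha": alpha}
        for name in METRIC_NAMES:
            row[name] = agg.mean[name]
            row[f"{name}_sd"] = agg.sd[name]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RankedCandidates:
    """Top-k unobserved lncRNAs for one disease, by fused score."""

    disease_id: str
    ranking: list[tuple[str, float]]
    k: int


def train_full_model(am: AssociationMatrix, config: PipelineConfig) -> EnsembleModel:
    """Train the fused ensemble on the whole catalog for candidate discovery."""
    from .data_io import assemble_dataset

    fact = svd_factorize(am, e=config.e)
    featurizer = PairFeaturizer(fact, scaling=config.scaling)
    ds = assemble_dataset(
        am,
        featurizer,
        mode=config.sampling_mode,
        neg_ratio=config.neg_ratio,
        seed=config.seed,
    )
    model = train_ensemble(
        ds, cnn_cfg=config.cnn, gbm_cfg=config.gbm, alpha=config.alpha,
        seed=config.seed,
    )
    model.featurizer = featurizer
    return model


def rank_candidates(
    model: EnsembleModel, am: AssociationMatrix, disease_id: str, k: int = 15
) -> RankedCandidates:
    """Rank the lncRNAs with no observed association to ``disease_id``.

    Scores every zero cell of the disease's column, sorts descending
    (ties broken by lncRNA index order) and truncates to ``k``.
    """
    if disease_id not in am.dis_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    if model.featurizer is None:
        raise ValueError("model carries no featurizer; train via train_full_model")
    j = am.dis_ids.index(disease_id)
    rows = np.flatnonzero(am.Y[:, j] == 0)
    if len(rows) == 0:
        return RankedCandidates(disease_id=disease_id, ranking=[], k=k)
    pairs = np.column_stack([rows, np.full(len(rows), j)])
    scores = model.predict(model.featurizer.pair_matrix(pairs))
    order = np.lexsort((rows, -scores))[:k]
    ranking = [(am.lnc_ids[rows[i]], float(scores[i])) for i in order]
    return RankedCandidates(disease_id=disease_id, ranking=ranking, k=k)
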