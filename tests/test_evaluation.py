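import numpy as np
import pytest

from ldaboost import (
    AssociationMatrix,
    compute_metrics,
    cross_validate,
    ablation_sweep,
    make_folds,
    rank_candidates,
    train_full_model,
)
from ldaboost.evaluation import DEFAULT_ALPHA_GRID, _prepare_fold
from ldaboost.svd_features import svd_factorize


# --- brute-force metric oracles -------------------------------------------


def oracle_metrics(y, s, threshold=0.5):
    """Confusion-matrix, pairwise-AUC and step-AUPR oracles by enumeration."""
    y = np.asarray(y)
    s = np.asarray(s)
    pred = (s >= threshold).astype(int)
    tp = np.sum((pred == 1) & (y == 1))
    fp = np.sum((pred == 1) & (y == 0))
    fn = np.sum((pred == 0) & (y == 1))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = np.mean(pred == y)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    auc = wins / (len(pos) * len(neg))

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    aupr, tp_c = 0.0, 0
    for k, yk in enumerate(ys, start=1):
        if yk == 1:
            tp_c += 1
            aupr += (tp_c / k) / len(pos)  # precision@k times recall step
    return dict(
        precision=precision, recall=recall, accuracy=accuracy,
        f1=f1, auc=auc, aupr=aupr,
    )


class TestMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(np.array([1, 0, 1, 0]), np.array([1, 0, 1, 0.0]))
        assert all(v == 1.0 for v in rep.as_dict().values())

    def test_hand_enumerated_example(self):
        rep = compute_metrics(
            np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.7, 0.1])
        )
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == 1.0
        assert rep.accuracy == 0.75
        assert rep.f1 == pytest.approx(0.8)
        assert rep.auc == 0.75

    def test_anti_classifier_auc_zero(self):
        y = np.array([1, 0, 1, 0])
        rep = compute_metrics(y, 1.0 - y)
        assert rep.auc == 0.0

    def test_matches_bruteforce_oracles(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = rng.integers(0, 2, 80)
            if len(np.unique(y)) < 2:
                continue
            s = rng.random(80)
            rep = compute_metrics(y, s).as_dict()
            ora = oracle_metrics(y, s)
            for name, v in ora.items():
                assert rep[name] == pytest.approx(v, abs=1e-9), name

    def test_single_class_ranking_metrics_nan(self):
        rep = compute_metrics(np.ones(4, int), np.array([0.9, 0.8, 0.7, 0.6]))
        assert np.isnan(rep.auc) and np.isnan(rep.aupr)
        assert rep.recall == 1.0


class TestFoldPlans:
    def test_even_partition_of_lncrnas(self, small_am):
        plan = make_folds(small_am, "lncrna", k=5, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert sum(sizes) == small_am.n
        assert max(sizes) - min(sizes) <= 1

    @pytest.mark.parametrize("mode", ["lncrna", "disease", "pair"])
    def test_folds_disjoint_and_cover(self, small_am, mode):
        plan = make_folds(small_am, mode, k=4, seed=1)
        allidx = np.concatenate(plan.folds)
        assert len(allidx) == len(np.unique(allidx))
        if mode == "pair":
            total = len(plan.pairs)
        else:
            total = small_am.n if mode == "lncrna" else small_am.m
        assert len(allidx) == total

    def test_k_exceeding_entity_count_rejected(self, small_am):
        with pytest.raises(ValueError):
            make_folds(small_am, "disease", k=small_am.m + 1, seed=0)

    def test_k_below_two_rejected(self, small_am):
        with pytest.raises(ValueError):
            make_folds(small_am, "pair", k=1, seed=0)

    def test_pair_mode_sample_is_balanced(self, small_am):
        plan = make_folds(small_am, "pair", k=5, seed=2, neg_ratio=1.0)
        labels = small_am.Y[plan.pairs[:, 0], plan.pairs[:, 1]]
        assert labels.sum() * 2 == len(labels)

    def test_cold_start_train_test_entity_disjointness(self, small_am):
        plan = make_folds(small_am, "lncrna", k=5, seed=3)
        for i, fold in enumerate(plan.folds):
            train = np.concatenate([f for j, f in enumerate(plan.folds) if j != i])
            assert len(np.intersect1d(train, fold)) == 0


class TestCrossValidation:
    def test_aggregate_is_arithmetic_mean_of_folds(self, small_am, tiny_config):
        plan = make_folds(small_am, "pair", k=4, seed=5)
        res = cross_validate(small_am, tiny_config, plan)
        assert len(res.reports) + len(res.skipped) == 4
        aucs = [r.auc for r in res.reports]
        assert res.mean["auc"] == pytest.approx(np.mean(aucs))
        assert res.sd["auc"] == pytest.approx(np.std(aucs, ddof=1))

    @pytest.mark.parametrize("mode", ["lncrna", "disease"])
    def test_entity_modes_run_and_score(self, small_am, tiny_config, mode):
        plan = make_folds(small_am, mode, k=4, seed=5)
        res = cross_validate(small_am, tiny_config, plan)
        assert res.reports, "at least one fold should be evaluable"
        for rep in res.reports:
            assert 0.0 <= rep.auc <= 1.0

    def test_masking_hides_test_positives_from_factorization(
        self, small_am, tiny_config
    ):
        plan = make_folds(small_am, "pair", k=4, seed=5)
        test_pairs = plan.pairs[plan.folds[0]]
        pos = test_pairs[small_am.Y[test_pairs[:, 0], test_pairs[:, 1]] == 1]
        Y_masked = small_am.Y.astype(float).copy()
        Y_masked[pos[:, 0], pos[:, 1]] = 0.0
        f1 = svd_factorize(Y_masked, e=tiny_config.e)
        # re-zeroing the already-masked positives changes nothing
        Y_again = Y_masked.copy()
        Y_again[pos[:, 0], pos[:, 1]] = 0.0
        f2 = svd_factorize(Y_again, e=tiny_config.e)
        assert np.array_equal(f1.U_e, f2.U_e)
        assert np.array_equal(f1.sigma, f2.sigma)

    def test_unmasked_mode_also_runs(self, small_am, tiny_config):
        tiny_config.mask = False
        plan = make_folds(small_am, "pair", k=4, seed=5)
        res = cross_validate(small_am, tiny_config, plan)
        assert res.reports


class TestAblation:
    def test_alpha_grid_default_and_endpoint_identity(self, small_am, tiny_config):
        assert DEFAULT_ALPHA_GRID == (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        plan = make_folds(small_am, "pair", k=3, seed=6)
        table = ablation_sweep(
            small_am, tiny_config, alphas=(0.0, 0.4, 1.0), plan=plan
        )
        ens0 = table[(table.variant == "ensemble") & (table.alpha == 0.0)]
        gbm = table[table.variant == "lightgbm"]
        for name in ("auc", "aupr", "accuracy"):
            assert ens0[name].iloc[0] == pytest.approx(gbm[name].iloc[0])
        ens1 = table[(table.variant == "ensemble") & (table.alpha == 1.0)]
        cnn = table[table.variant == "adaboost_cnn"]
        assert ens1["auc"].iloc[0] == pytest.approx(cnn["auc"].iloc[0])
        assert set(table.variant) == {
            "ensemble", "adaboost_cnn", "adaboost", "lightgbm",
        }

    def test_invalid_alpha_rejected(self, small_am, tiny_config):
        with pytest.raises(ValueError):
            ablation_sweep(small_am, tiny_config, alphas=(0.5, 1.2))


class TestRanking:
    @pytest.fixture
    def trained(self, small_am, tiny_config):
        return train_full_model(small_am, tiny_config)

    def test_known_positives_excluded(self, trained, small_am):
        dis = small_am.dis_ids[0]
        ranked = rank_candidates(trained, small_am, dis, k=small_am.n)
        known = {
            small_am.lnc_ids[i]
            for i in np.flatnonzero(small_am.Y[:, 0] == 1)
        }
        names = [name for name, _ in ranked.ranking]
        assert not known & set(names)
        assert len(names) == small_am.n - len(known)

    def test_scores_non_increasing_and_truncated(self, trained, small_am):
        ranked = rank_candidates(trained, small_am, small_am.dis_ids[1], k=5)
        scores = [s for _, s in ranked.ranking]
        assert len(scores) <= 5
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_default_k_is_15(self, trained, small_am):
        ranked = rank_candidates(trained, small_am, small_am.dis_ids[2])
        assert ranked.k == 15
        assert len(ranked.ranking) <= 15

    def test_unknown_disease_rejected(self, trained, small_am):
        with pytest.raises(KeyError):
            rank_candidates(trained, small_am, "NO_SUCH_DISEASE")


class TestPrepareFold:
    def test_skips_fold_without_test_positives(self, tiny_config):
        # one lncRNA holds every association; holding it out leaves no
        # training positives and its fold has no negatives elsewhere
        Y = np.zeros((4, 6), dtype=int)
        Y[0] = 1
        am = AssociationMatrix(
            [f"L{i}" for i in range(4)], [f"D{j}" for j in range(6)], Y
        )
        plan = make_folds(am, "lncrna", k=4, seed=0)
        results = [
            _prepare_fold(am, tiny_config, plan, i) for i in range(plan.k)
        ]
        assert any(r is None for r in results)
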