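"""Accuracy protocol: confusion, curves, selfloop policy, similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import grnbench as gb
from grnbench.metrics import (
    ConfusionCounts,
    apply_selfloop_policy,
    confusion,
    f1,
    mcc,
    precision,
    recall,
    threshold_sweep,
    fpr as fpr_of,
)
from grnbench.networks import Network
from conftest import dense_grn


def brute_force_curve(scores: np.ndarray, gold: np.ndarray):
    """Enumeration oracle: loop every unique cutoff, count with set arithmetic,
    integrate with the same anchoring conventions."""
    pairs = [(i, j) for i in range(scores.shape[0]) for j in range(scores.shape[1])]
    gold_set = {p for p in pairs if gold[p]}
    points = []
    for cut in sorted({abs(scores[p]) for p in pairs}, reverse=True):
        pred = {p for p in pairs if abs(scores[p]) >= cut}
        c = confusion(gold_set, pred, len(pairs))
        points.append((recall(c), precision(c), fpr_of(c), f1(c), mcc(c)))
    rec = np.array([p[0] for p in points])
    prec = np.array([p[1] for p in points])
    fprs = np.array([p[2] for p in points])
    au_pr = np.trapezoid(
        np.concatenate([[prec[0]], prec]), np.concatenate([[0.0], rec])
    )
    au_roc = np.trapezoid(
        np.concatenate([[0.0], rec, [1.0]]), np.concatenate([[0.0], fprs, [1.0]])
    )
    return points, float(au_pr), float(au_roc)


class TestConfusionAndScalars:
    def test_three_gene_enumeration_example(self):
        gold = {(1, 0), (2, 1)}  # edges 1->2, 2->3 as (target, regulator)
        pred = {(1, 0), (1, 2)}
        c = confusion(gold, pred, 6)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 3)

    def test_perfect_and_empty_predictions(self):
        gold = {(0, 1), (1, 0)}
        perfect = confusion(gold, gold, 4)
        assert perfect.fp == perfect.fn == 0
        empty = confusion(gold, set(), 4)
        assert (empty.tp, empty.fp, empty.fn) == (0, 0, 2)

    def test_scalar_metric_conventions(self):
        assert mcc(ConfusionCounts(1, 0, 1, 0)) == 1.0
        assert f1(ConfusionCounts(1, 0, 1, 0)) == 1.0
        assert mcc(ConfusionCounts(5, 5, 5, 5)) == 0.0
        expected = 264 / np.sqrt(4 * 9 * 91 * 96)
        assert mcc(ConfusionCounts(3, 1, 90, 6)) == pytest.approx(expected)
        assert f1(ConfusionCounts(0, 0, 10, 0)) == 0.0
        assert mcc(ConfusionCounts(0, 0, 10, 5)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_scalar_metric_ranges(self, counts):
        c = ConfusionCounts(*counts)
        assert 0.0 <= f1(c) <= 1.0
        assert -1.0 <= mcc(c) <= 1.0
        assert 0.0 <= precision(c) <= 1.0
        assert 0.0 <= recall(c) <= 1.0


class TestSelfloopPolicy:
    def test_pair_counts_by_category(self):
        net = gb.generate_scale_free_network(100, 3.0, seed=0)
        p_pred = dense_grn(np.ones((100, 100)), "p_based")
        np_pred = dense_grn(np.ones((100, 100)), "non_p_based")
        assert apply_selfloop_policy(net, p_pred)[2] == 10_000
        assert apply_selfloop_policy(net, np_pred)[2] == 9_900

    def test_diagonal_not_charged_to_non_p_methods(self):
        """Selfloops in the gold never count as FN for expression-only methods."""
        net = gb.generate_scale_free_network(10, 2.0, seed=1)
        scores = np.abs(net.weights.copy())
        np.fill_diagonal(scores, 0.0)  # a non-P method cannot predict selfloops
        res = gb.evaluate(net, dense_grn(scores, "non_p_based"))
        assert res.n_gold == net.n_links(include_diagonal=False)
        assert res.aupr == 1.0

    def test_strip_all_mode_removes_diagonal_everywhere(self):
        net = gb.generate_scale_free_network(10, 2.0, seed=2)
        res = gb.evaluate(net, dense_grn(np.abs(net.weights)), "strip_all")
        assert res.n_evaluated == 90
        assert all(i != j for i, j in res.max_f1_edges)

    def test_gene_set_mismatch_rejected(self):
        net = gb.generate_scale_free_network(5, 2.0, seed=0)
        with pytest.raises(ValueError):
            apply_selfloop_policy(net, dense_grn(np.ones((4, 4))))


class TestThresholdSweep:
    def test_unique_value_counting(self):
        grn = dense_grn([[0.9, 0.5], [0.5, 0.1]])
        nets = threshold_sweep(grn)
        assert [int(n.sum()) for n in nets] == [1, 3, 4]

    def test_monotonic_nesting(self):
        rng = np.random.default_rng(0)
        grn = dense_grn(rng.normal(size=(10, 10)))
        nets = threshold_sweep(grn)
        for sparse, dense in zip(nets, nets[1:]):
            assert np.all(dense[sparse])  # every sparser net contained in denser

    def test_penalty_sweep_passes_through(self, small_system):
        net, design, x = small_system
        grn = gb.infer_penalized(x, design, 1.0)
        res = gb.evaluate(net, grn)
        assert res.recall.size == 30

    def test_all_zero_prediction_warns(self):
        grn = dense_grn(np.zeros((3, 3)))
        nets = threshold_sweep(grn)
        assert len(nets) == 1 and not nets[0].any()


class TestCurves:
    def test_perfect_ranking(self):
        net = gb.generate_scale_free_network(10, 2.0, seed=3)
        res = gb.evaluate(net, dense_grn(np.abs(net.weights)))
        assert res.aupr == 1.0
        assert res.auroc == 1.0
        assert res.max_f1 == 1.0
        assert res.max_f1_edges == net.edges()

    @pytest.mark.parametrize("seed", range(8))
    def test_against_brute_force_enumeration(self, seed):
        """Vectorized sweep equals the enumeration oracle on 5-gene instances."""
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=(5, 5)) * (rng.random((5, 5)) < 0.7)
        gold = rng.random((5, 5)) < 0.3
        gold_net = Network(weights=gold.astype(float) - 2 * np.eye(5))
        res = gb.evaluate(gold_net, dense_grn(scores))
        points, au_pr, au_roc = brute_force_curve(scores, gold | np.eye(5, dtype=bool))
        np.testing.assert_allclose(res.recall, [p[0] for p in points])
        np.testing.assert_allclose(res.precision, [p[1] for p in points])
        np.testing.assert_allclose(res.f1, [p[3] for p in points])
        np.testing.assert_allclose(res.mcc, [p[4] for p in points])
        assert res.aupr == pytest.approx(au_pr)
        assert res.auroc == pytest.approx(au_roc)

    @pytest.mark.parametrize("seed", range(5))
    def test_auroc_against_sklearn(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.abs(rng.normal(size=(8, 8)))
        gold = rng.random((8, 8)) < 0.25
        gold_net = Network(weights=gold.astype(float) - 2 * np.eye(8))
        res = gb.evaluate(gold_net, dense_grn(scores))
        gold_full = gold | np.eye(8, dtype=bool)
        assert res.auroc == pytest.approx(
            roc_auc_score(gold_full.ravel(), scores.ravel())
        )

    def test_random_scores_hit_the_random_baselines(self):
        """Random ranking: AUROC 0.5 +- 0.05, AUPR within [0.5, 2] x prevalence."""
        net = gb.generate_scale_free_network(100, 3.0, seed=4)
        auprs, aurocs = [], []
        for seed in range(20):
            scores = np.abs(np.random.default_rng(seed).normal(size=(100, 100)))
            res = gb.evaluate(net, dense_grn(scores))
            auprs.append(res.aupr)
            aurocs.append(res.auroc)
        prevalence = net.n_links() / 10_000
        assert 0.45 <= np.mean(aurocs) <= 0.55
        assert 0.5 * prevalence <= np.mean(auprs) <= 2 * prevalence

    def test_invariance_under_monotone_score_transform(self):
        net = gb.generate_scale_free_network(20, 3.0, seed=5)
        scores = np.abs(np.random.default_rng(1).normal(size=(20, 20)))
        a = gb.evaluate(net, dense_grn(scores))
        b = gb.evaluate(net, dense_grn(np.expm1(3 * scores)))
        assert a.aupr == pytest.approx(b.aupr)
        assert a.auroc == pytest.approx(b.auroc)
        assert a.max_f1 == pytest.approx(b.max_f1)

    def test_penalty_sweep_agrees_with_threshold_sweep(self, small_system):
        """30 quantile-threshold networks vs the full unique-value sweep of the
        same dense scores land within 0.05 AUPR."""
        net, design, x = small_system
        y = gb.add_noise(x, gb.NoiseSpec.for_expression(x, 0.1), seed=6)
        dense = gb.infer_least_squares(y, design)
        full = gb.evaluate(net, dense)
        scores = np.abs(dense.dense_weights)
        cutoffs = np.quantile(scores, np.linspace(0.0, 0.999, 30))
        sweep = gb.ScoredGRN(
            method_name="ls30",
            category="p_based",
            sweep=[scores >= c for c in sorted(cutoffs)],
        )
        coarse = gb.evaluate(net, sweep)
        assert abs(full.aupr - coarse.aupr) < 0.05

    def test_undirected_prediction_pays_direction_penalty(self):
        """Symmetrized true scores evaluated directed lose AUPR vs the
        direction-aware scores."""
        net = gb.generate_scale_free_network(15, 3.0, seed=6)
        truth = np.abs(net.weights)
        np.fill_diagonal(truth, 0.0)
        sym = np.maximum(truth, truth.T)
        directed = gb.evaluate(net, dense_grn(truth, "non_p_based"))
        undirected = gb.evaluate(
            net, dense_grn(sym, "non_p_based", directed=False)
        )
        assert undirected.aupr <= directed.aupr


class TestMaxF1AndSimilarity:
    def test_max_f1_network_picks_dominating_middle_point(self):
        gold = Network(
            weights=np.array([[-1.0, 1.0, 0.0], [0.0, -1.0, 1.0], [0.0, 0.0, -1.0]])
        )
        full = np.ones((3, 3), dtype=bool)
        middle = gold.weights != 0
        sparse = np.zeros((3, 3), dtype=bool)
        sparse[0, 1] = True
        grn = gb.ScoredGRN(
            method_name="hand", category="p_based", sweep=[full, middle, sparse]
        )
        res = gb.evaluate(gold, grn)
        # oracle: direct F1 of all three points picks the exact-support middle
        assert res.max_f1 == 1.0
        assert res.max_f1_edges == gold.edges()

    def test_f1_ties_break_toward_sparser_network(self):
        gold = Network(weights=np.diag([-1.0, -1.0]) + np.array([[0, 1], [0, 0.0]]))
        a = np.zeros((2, 2), dtype=bool)
        a[0, 1] = True
        b = a.copy()
        grn = gb.ScoredGRN(method_name="tie", category="p_based", sweep=[b, a])
        res = gb.evaluate(gold, grn)
        assert res.max_f1_edges == frozenset({(0, 1)})

    def test_jaccard_conventions(self):
        assert gb.jaccard(frozenset("abc"), frozenset("abc")) == 1.0
        assert gb.jaccard(frozenset("ab"), frozenset("cd")) == 0.0
        assert gb.jaccard(frozenset("abc"), frozenset("bcd")) == 0.5
        assert gb.jaccard(frozenset(), frozenset()) == 1.0

    def test_true_fraction_conventions(self):
        gold = frozenset({(0, 1), (1, 2)})
        assert gb.true_fraction({(0, 1)}, {(0, 1)}, gold) == 1.0
        assert gb.true_fraction({(2, 0)}, {(2, 0)}, gold) == 0.0
        assert gb.true_fraction({(0, 1), (2, 0)}, {(0, 1), (2, 0)}, gold) == 0.5
        assert gb.true_fraction({(0, 1)}, {(2, 2)}, gold) is None

    @settings(max_examples=100, derandomize=True)
    @given(
        st.sets(st.integers(0, 15)),
        st.sets(st.integers(0, 15)),
    )
    def test_jaccard_properties(self, a, b):
        a, b = frozenset(a), frozenset(b)
        val = gb.jaccard(a, b)
        assert 0.0 <= val <= 1.0
        assert val == gb.jaccard(b, a)
        if a == b:
            assert val == 1.0
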