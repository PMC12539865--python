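import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chromascreen import coexpression as cx
from chromascreen.coexpression import ExpressionMatrix
from chromascreen.io_formats import ValidationError
from chromascreen.synthetic_data import ModuleSpec, make_expression


def _expr_from_log(values):
    """Wrap a log2-scale signal matrix as counts (inverse of the log the
    network operations apply)."""
    values = np.asarray(values, dtype=float)
    counts = 2.0**values - 1.0
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        np.clip(counts, 0, None),
    )


def _brute_force_tom(a):
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestAdjacency:
    def test_perfectly_correlated_pair_any_power(self, rng):
        x = rng.normal(size=50)
        expr = _expr_from_log(np.vstack([5 + x, 7 + 2 * x]))
        for beta in (1, 7, 12):
            a = cx.adjacency(expr, beta)
            assert a[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_pair_small_at_high_power(self, rng):
        expr = _expr_from_log(5 + rng.normal(size=(2, 1000)))
        assert cx.adjacency(expr, 7)[0, 1] < 0.1

    def test_monotone_decreasing_in_power(self, rng):
        expr = _expr_from_log(5 + rng.normal(size=(5, 30)))
        a3, a7 = cx.adjacency(expr, 3), cx.adjacency(expr, 7)
        off = ~np.eye(5, dtype=bool)
        assert np.all(a7[off] <= a3[off] + 1e-12)

    def test_constant_gene_rejected_by_name(self, rng):
        vals = 5 + rng.normal(size=(3, 10))
        vals[1] = 4.0
        with pytest.raises(ValidationError, match="g1"):
            cx.adjacency(_expr_from_log(vals), 7)


class TestTOM:
    def test_hand_worked_three_gene_example(self):
        a = np.array([[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1]])
        tom = cx.tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-12)

    def test_zero_offdiagonal_adjacency(self):
        tom = cx.tom_similarity(np.eye(4))
        np.testing.assert_allclose(tom, np.eye(4))

    def test_matches_triple_loop_brute_force(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 1, (10, 10))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(
                cx.tom_similarity(a), _brute_force_tom(a), atol=1e-10
            )

    def test_bounded_in_unit_interval(self, rng):
        a = rng.uniform(0, 1, (15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_similarity(a)
        assert np.all(tom >= 0) and np.all(tom <= 1)


class TestSoftThreshold:
    def test_power_one_adjacency_is_abs_correlation(self, rng):
        expr = _expr_from_log(5 + rng.normal(size=(6, 40)))
        a = cx.adjacency(expr, 1)
        cor = np.abs(np.corrcoef(np.log2(expr.values + 1)))
        np.testing.assert_allclose(a, cor, atol=1e-12)

    def test_chosen_power_reaches_target_on_tuned_generator(self):
        expr, _ = make_expression(seed=2)
        fit = cx.pick_soft_threshold(expr)
        assert fit.r2_signed[fit.powers.index(fit.chosen)] >= 0.8

    def test_uniformly_distributed_connectivity_scores_low(self, rng):
        # flat k histogram: frequency does not fall with connectivity, so
        # the signed fit index cannot indicate scale-freeness
        k = np.linspace(1.0, 50.0, 400)
        assert cx.scale_free_r2(k) < 0.5

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValidationError):
            cx.scale_free_r2(np.full(50, 3.0))


class TestDetectModules:
    def test_planted_modules_recovered(self):
        spec = [ModuleSpec(30, min_loading=0.7), ModuleSpec(30, min_loading=0.7),
                ModuleSpec(30, min_loading=0.7)]
        expr, truth = make_expression(n_genes=150, module_spec=spec, seed=5)
        beta = cx.pick_soft_threshold(expr).chosen
        tom = cx.tom_similarity(cx.adjacency(expr, beta))
        ms = cx.detect_modules(tom, expr.gene_ids)
        true_labels = [truth.module_labels[g] for g in expr.gene_ids]
        assert len(ms.module_ids) >= 3
        assert adjusted_rand_score(true_labels, ms.labels) >= 0.9

    def test_identical_genes_form_one_module(self, rng):
        base = 6 + rng.normal(size=40)
        vals = np.tile(base, (20, 1)) + rng.normal(scale=1e-3, size=(20, 40))
        ms = cx.detect_modules(
            cx.tom_similarity(cx.adjacency(_expr_from_log(vals), 7)),
            [f"g{i}" for i in range(20)],
        )
        assert list(np.unique(ms.labels)) == [1]

    def test_min_size_larger_than_n_genes_leaves_all_unassigned(self, rng):
        vals = 5 + rng.normal(size=(10, 20))
        tom = cx.tom_similarity(cx.adjacency(_expr_from_log(vals), 7))
        ms = cx.detect_modules(tom, [f"g{i}" for i in range(10)], min_size=50)
        assert (ms.labels == 0).all()

    def test_gene_order_permutation_equivariance(self, rng):
        expr, _ = make_expression(n_genes=120,
                                  module_spec=[ModuleSpec(30), ModuleSpec(30)],
                                  seed=8)
        tom = cx.tom_similarity(cx.adjacency(expr, 7))
        ms = cx.detect_modules(tom, expr.gene_ids)
        perm = rng.permutation(expr.n_genes)
        expr_p = ExpressionMatrix(
            [expr.gene_ids[i] for i in perm], expr.sample_ids, expr.values[perm]
        )
        tom_p = cx.tom_similarity(cx.adjacency(expr_p, 7))
        ms_p = cx.detect_modules(tom_p, expr_p.gene_ids)
        by_gene = dict(zip(ms.gene_ids, ms.labels))
        by_gene_p = dict(zip(ms_p.gene_ids, ms_p.labels))
        lab = [by_gene[g] for g in expr.gene_ids]
        lab_p = [by_gene_p[g] for g in expr.gene_ids]
        assert adjusted_rand_score(lab, lab_p) == pytest.approx(1.0)


class TestEigengenes:
    def test_identical_members_give_standardized_common_profile(self, rng):
        base = 6 + rng.normal(size=30)
        vals = np.tile(base, (5, 1))
        expr = _expr_from_log(vals)
        eg = cx.module_eigengene(expr, np.ones(5, dtype=int))
        logv = np.log2(expr.values + 1)[0]
        expect = (logv - logv.mean()) / logv.std()
        np.testing.assert_allclose(eg.loc[1].to_numpy(), expect, atol=1e-6)

    def test_sign_oriented_toward_members(self, rng):
        expr, _ = make_expression(n_genes=100, module_spec=[ModuleSpec(40)], seed=3)
        labels = np.array([1] * 40 + [0] * 60)
        eg = cx.module_eigengene(expr, labels)
        logv = np.log2(expr.values + 1)[:40]
        cors = [np.corrcoef(eg.loc[1], row)[0, 1] for row in logv]
        assert np.mean(cors) >= 0

    def test_recovers_planted_factor(self):
        expr, truth = make_expression(n_genes=80, module_spec=[ModuleSpec(40)], seed=4)
        labels = np.array(
            [truth.module_labels[g] for g in expr.gene_ids], dtype=int
        )
        eg = cx.module_eigengene(expr, labels)
        r = np.corrcoef(eg.loc[1], truth.factors[1])[0, 1]
        assert abs(r) >= 0.9


class TestMergeModules:
    def test_single_module_unchanged(self):
        expr, _ = make_expression(n_genes=60, module_spec=[ModuleSpec(30)], seed=6)
        ms = cx.ModuleSet(expr.gene_ids, np.array([1] * 30 + [0] * 30))
        merged = cx.merge_modules(expr, ms)
        assert list(merged.labels[:30]) == [1] * 30

    def test_split_module_remerged(self):
        expr, truth = make_expression(n_genes=80, module_spec=[ModuleSpec(40)], seed=7)
        labels = np.array([truth.module_labels[g] for g in expr.gene_ids])
        split = labels.copy()
        members = np.nonzero(labels == 1)[0]
        split[members[: len(members) // 2]] = 2
        merged = cx.merge_modules(expr, cx.ModuleSet(expr.gene_ids, split))
        assert len(merged.module_ids) == 1
        assert merged.merge_history

    def test_independent_factors_not_merged(self):
        expr, truth = make_expression(
            n_genes=100, module_spec=[ModuleSpec(40), ModuleSpec(40)], seed=9
        )
        labels = np.array([truth.module_labels[g] for g in expr.gene_ids])
        merged = cx.merge_modules(expr, cx.ModuleSet(expr.gene_ids, labels))
        assert len(merged.module_ids) == 2

    def test_final_eigengene_correlations_below_threshold(self):
        expr, truth = make_expression(seed=10)
        labels = np.array([truth.module_labels[g] for g in expr.gene_ids])
        merged = cx.merge_modules(expr, cx.ModuleSet(expr.gene_ids, labels))
        if len(merged.module_ids) > 1:
            cor = np.corrcoef(merged.eigengenes.to_numpy())
            off = cor[~np.eye(len(cor), dtype=bool)]
            assert off.max() <= 0.75


class TestTraitsAndHubs:
    def _eg(self, rows, samples):
        return pd.DataFrame(rows, index=range(1, len(rows) + 1), columns=samples)

    def test_eigengene_equal_and_opposite_to_trait(self):
        samples = [f"s{i}" for i in range(8)]
        t = np.arange(8.0)
        eg = self._eg([t, -t], samples)
        traits = pd.DataFrame({"trait": t}, index=samples)
        out = cx.module_trait_correlation(eg, traits).set_index("module")
        assert out.loc[1, "r"] == pytest.approx(1.0)
        assert out.loc[2, "r"] == pytest.approx(-1.0)

    def test_zero_variance_trait_rejected(self):
        samples = [f"s{i}" for i in range(5)]
        eg = self._eg([np.arange(5.0)], samples)
        with pytest.raises(ValidationError):
            cx.module_trait_correlation(
                eg, pd.DataFrame({"t": np.ones(5)}, index=samples)
            )

    def test_planted_anticorrelated_module_most_negative(self):
        expr, truth = make_expression(seed=12)
        labels = np.array([truth.module_labels[g] for g in expr.gene_ids])
        ms = cx.merge_modules(expr, cx.ModuleSet(expr.gene_ids, labels))
        out = cx.module_trait_correlation(ms.eigengenes, truth.traits)
        red = out[out.trait == "redness"].set_index("module")["r"]
        most_neg = red.idxmin()
        m1 = set(g for g, l in truth.module_labels.items() if l == 1)
        assert len(set(ms.members(most_neg)) & m1) > len(m1) / 2

    def test_gene_identical_to_eigengene_is_hub(self):
        expr, truth = make_expression(n_genes=60, module_spec=[ModuleSpec(30)], seed=13)
        labels = np.array([truth.module_labels[g] for g in expr.gene_ids])
        ms = cx.merge_modules(expr, cx.ModuleSet(expr.gene_ids, labels))
        kme = ms.kme
        hub_gene = expr.gene_ids[0]  # highest-loading planted gene
        assert abs(kme.loc[hub_gene, 1]) > 0.8
        assert hub_gene in cx.hub_genes(ms)[1]

    def test_no_hubs_below_cut(self):
        expr, truth = make_expression(n_genes=60, module_spec=[ModuleSpec(30)], seed=14)
        labels = np.array([truth.module_labels[g] for g in expr.gene_ids])
        ms = cx.merge_modules(expr, cx.ModuleSet(expr.gene_ids, labels))
        assert cx.hub_genes(ms, mm_cut=1.0) == {1: []}

    def test_planted_hubs_recovered(self):
        expr, truth = make_expression(seed=15)
        fit = cx.pick_soft_threshold(expr)
        tom = cx.tom_similarity(cx.adjacency(expr, fit.chosen))
        ms = cx.merge_modules(expr, cx.detect_modules(tom, expr.gene_ids))
        found = set(g for v in cx.hub_genes(ms).values() for g in v)
        planted = set(g for v in truth.hub_genes.values() for g in v)
        assert len(found & planted) / len(planted) >= 0.9
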