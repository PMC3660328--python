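"""Nested LOOCV classification: ranking, calibration, leakage guards."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from brcaness.classify import (
    LinearSVM,
    _lexical_ranks,
    adjust_probability,
    inner_select_n,
    loocv_classify,
    loocv_fixed_genes,
    rank_genes,
    select_smallest_best,
    stratified_classify,
)
from brcaness.config import RunConfig
from brcaness.synthetic import CohortSpec, simulate_cohort

from conftest import make_expr, planted_cohort


class TestRankGenes:
    def test_planted_gene_usually_first(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            expr = make_expr(200, 40, seed=seed)
            expr.iloc[0, :20] += 3.0  # 3 sd shift in cases
            ranking = rank_genes(expr, [True] * 20 + [False] * 20)
            hits += ranking.index[0] == expr.index[0]
        assert hits >= 48  # >= 95% of repetitions

    def test_permutation_invariance(self):
        expr = make_expr(100, 30, seed=1)
        labels = np.array([True] * 10 + [False] * 20)
        perm = np.random.default_rng(2).permutation(30)
        r1 = rank_genes(expr, labels)
        r2 = rank_genes(expr.iloc[:, perm], labels[perm])
        assert list(r1.index) == list(r2.index)

    def test_signed_statistic_kept(self):
        expr = make_expr(50, 20, seed=3)
        expr.iloc[0, :10] += 5.0
        expr.iloc[1, 10:] += 5.0
        ranking = rank_genes(expr, [True] * 10 + [False] * 10)
        assert ranking.loc[expr.index[0], "t_statistic"] > 0
        assert ranking.loc[expr.index[1], "t_statistic"] < 0

    def test_tie_break_is_lexical(self):
        symbols = np.array(["b", "a", "c"])
        ranks = _lexical_ranks(symbols)
        assert list(ranks) == [1, 0, 2]


class TestAdjustProbability:
    def test_equal_priors_identity(self):
        for p in np.linspace(0, 1, 11):
            assert adjust_probability(p, 10, 10) == pytest.approx(p)

    def test_stated_formula_example(self):
        # p_raw 0.5 with prior pi1 = 0.2 -> 0.8
        assert adjust_probability(0.5, 2, 8) == pytest.approx(0.8)

    def test_boundaries_fixed(self):
        assert adjust_probability(0.0, 3, 17) == 0.0
        assert adjust_probability(1.0, 3, 17) == 1.0

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        out = adjust_probability(grid, 5, 45)
        assert (np.diff(out) > 0).all()


class TestLinearSVM:
    def test_decision_matches_sklearn_svc(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(40, 15))
            y = rng.random(40) < 0.4
            if y.all() or not y.any():
                continue
            x[y] += 0.8
            ours = LinearSVM(1.0).fit(x, y)
            ref = SVC(kernel="linear", C=1.0).fit(x, y.astype(int))
            np.testing.assert_allclose(
                ours.decision_function(x), ref.decision_function(x), atol=1e-6
            )


class TestSelectSmallestBest:
    def test_lowest_count_at_highest_accuracy(self):
        assert select_smallest_best([10, 20, 30], [0.80, 0.90, 0.90]) == 20

    def test_single_entry(self):
        assert select_smallest_best([25], [0.6]) == 25

    def test_order_independent(self):
        assert select_smallest_best([30, 10, 20], [0.9, 0.8, 0.9]) == 20


class TestInnerSelectN:
    def test_single_grid_value_returned(self):
        expr, labels, _ = planted_cohort(n_genes=100, seed=0)
        cfg = RunConfig(seed=0, gene_count_grid=[10])
        values = expr.to_numpy()
        n = inner_select_n(
            values, (labels == "case").to_numpy(),
            _lexical_ranks(expr.index.to_numpy(str)), cfg,
        )
        assert n == 10

    def test_grid_capped_to_gene_count(self):
        expr, labels, _ = planted_cohort(n_genes=20, n_effect=5, seed=1)
        cfg = RunConfig(seed=0, gene_count_grid=[5, 15, 500])
        n = inner_select_n(
            expr.to_numpy(), (labels == "case").to_numpy(),
            _lexical_ranks(expr.index.to_numpy(str)), cfg,
        )
        assert n in (5, 15)


class TestLoocv:
    def test_planted_effect_recovered(self, small_config):
        expr, labels, _ = planted_cohort(
            n_genes=600, n_cases=15, n_controls=25, n_effect=30, delta=1.5, seed=2
        )
        result = loocv_classify(expr, labels, "case", small_config)
        assert result.balanced_accuracy >= 0.85
        assert result.fisher_p < 1e-3

    def test_confusion_counts_conserve_classes(self, small_config):
        expr, labels, _ = planted_cohort(n_genes=200, seed=3)
        result = loocv_classify(expr, labels, "case", small_config)
        assert result.tp + result.fn == (labels == "case").sum()
        assert result.tn + result.fp == (labels == "control").sum()
        assert set(result.chosen_gene_counts) <= set(small_config.gene_count_grid)

    def test_bit_reproducible_under_fixed_seed(self, small_config):
        expr, labels, _ = planted_cohort(n_genes=150, seed=4)
        r1 = loocv_classify(expr, labels, "case", small_config)
        r2 = loocv_classify(expr, labels, "case", small_config)
        assert r1.probabilities == r2.probabilities
        assert r1.predicted_labels == r2.predicted_labels

    def test_accuracy_nondecreasing_in_effect_size(self):
        cfg = RunConfig(seed=0, gene_count_grid=[5, 15, 30])
        bas = []
        for delta in (0.0, 1.0, 2.5):
            vals = []
            for seed in (0, 1, 2):
                expr, labels, _ = planted_cohort(
                    n_genes=300, n_cases=12, n_controls=18, n_effect=20,
                    delta=delta, seed=10 + seed,
                )
                vals.append(loocv_classify(expr, labels, "case", cfg).balanced_accuracy)
            bas.append(np.mean(vals))
        assert bas[0] - 0.15 <= bas[1] and bas[1] <= bas[2] + 0.1
        assert bas[2] > bas[0]

    def test_leaky_variant_inflates_null_accuracy(self):
        # structural check that the nesting matters: on pure noise, ranking
        # and size selection on the full data must look far better than the
        # leakage-free nested procedure
        cfg = RunConfig(seed=0, gene_count_grid=[5, 15, 30])
        nested, leaky = [], []
        for seed in range(3):
            expr = make_expr(400, 36, seed=100 + seed)
            labels = pd.Series(["case"] * 12 + ["control"] * 24, index=expr.columns)
            nested.append(loocv_classify(expr, labels, "case", cfg).balanced_accuracy)
            leaky.append(
                loocv_classify(expr, labels, "case", cfg, leaky=True).balanced_accuracy
            )
        assert np.mean(leaky) > np.mean(nested) + 0.1
        assert np.mean(leaky) > 0.6

    def test_missing_class_rejected(self, small_config):
        expr = make_expr(50, 10, seed=5)
        labels = pd.Series(["case"] * 10, index=expr.columns)
        with pytest.raises(ValueError):
            loocv_classify(expr, labels, "case", small_config)


class TestFixedGeneLoocv:
    def test_uses_exactly_given_genes(self, small_config):
        expr, labels, effect = planted_cohort(n_genes=200, seed=6)
        result = loocv_fixed_genes(expr, labels, "case", effect, small_config)
        assert result.balanced_accuracy >= 0.8

    def test_absent_gene_rejected(self, small_config):
        expr, labels, _ = planted_cohort(n_genes=50, seed=7)
        with pytest.raises(KeyError):
            loocv_fixed_genes(expr, labels, "case", ["NOT_A_GENE"], small_config)


class TestStratified:
    def _cohort(self, seed=0):
        spec = CohortSpec(n_genes=800, effect_genes=40, seed=seed)
        return simulate_cohort(spec)

    def test_stratified_uses_only_stratum_samples(self):
        expr, ann, _ = self._cohort()
        cfg = RunConfig(seed=0, gene_count_grid=[5, 15, 30])
        result = stratified_classify(expr, ann, "basal", "BRCA1", cfg)
        in_stratum = ann[(ann.subtype == "basal") & ann.group.isin(["BRCA1", "sporadic"])]
        assert set(result.sample_ids) == set(in_stratum.index)

    def test_stratum_without_cases_rejected(self):
        expr, ann, _ = self._cohort()
        cfg = RunConfig(seed=0, gene_count_grid=[5])
        with pytest.raises(ValueError):
            stratified_classify(expr, ann, "normal_like", "BRCA1", cfg)
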