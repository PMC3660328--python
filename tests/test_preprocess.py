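"""Two-color preprocessing: normexp, MA-loess, quantile, probe collapsing."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from brcaness.config import RunConfig
from brcaness.containers import ValidationError
from brcaness.preprocess import (
    NormexpParams,
    collapse_probes,
    ma_loess_normalize,
    normexp_correct,
    normexp_fit,
    preprocess_pipeline,
    quantile_normalize,
)
from brcaness.synthetic import simulate_two_color


def conditional_mean_numeric(x, p: NormexpParams):
    """E[S | X = x] by direct numerical integration of the convolution."""
    def integrand_num(s):
        return s * sps.expon.pdf(s, scale=p.alpha) * sps.norm.pdf(x - s, p.mu, p.sigma)

    def integrand_den(s):
        return sps.expon.pdf(s, scale=p.alpha) * sps.norm.pdf(x - s, p.mu, p.sigma)

    hi = max(x - p.mu + 10 * p.sigma, 10 * p.alpha)
    num, _ = integrate.quad(integrand_num, 0, hi, limit=200)
    den, _ = integrate.quad(integrand_den, 0, hi, limit=200)
    return num / den


class TestNormexpFit:
    def test_parameter_recovery_on_simulated_convolution(self):
        rng = np.random.default_rng(42)
        x = rng.exponential(1000, 10000) + rng.normal(200, 30, 10000)
        p = normexp_fit(x)
        assert p.mu == pytest.approx(200, rel=0.05)
        assert p.alpha == pytest.approx(1000, rel=0.05)
        # sigma is weakly identified (sampling sd ~7% at this n); allow 3 sds
        assert p.sigma == pytest.approx(30, rel=0.25)

    def test_location_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(800, 5000) + rng.normal(150, 25, 5000)
        p0 = normexp_fit(x)
        p1 = normexp_fit(x + 500.0)
        assert p1.mu - p0.mu == pytest.approx(500.0, abs=5.0)
        assert p1.sigma == pytest.approx(p0.sigma, rel=0.02)
        assert p1.alpha == pytest.approx(p0.alpha, rel=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normexp_fit(np.full(500, 7.0))

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            normexp_fit(np.arange(50, dtype=float))


class TestNormexpCorrect:
    P = NormexpParams(200.0, 30.0, 1000.0)

    def test_outputs_strictly_positive(self):
        x = np.linspace(-400, 4000, 200)
        assert (normexp_correct(x, self.P) > 0).all()

    def test_monotone_nondecreasing(self):
        x = np.linspace(-400, 4000, 500)
        assert (np.diff(normexp_correct(x, self.P)) >= 0).all()

    def test_large_x_limit_matches_numeric_integration(self):
        for x in (1500.0, 3000.0):
            got = normexp_correct(np.array([x]), self.P)[0]
            want = conditional_mean_numeric(x, self.P)
            assert got == pytest.approx(want, rel=1e-6)
        # far above background the correction approaches x - mu
        x = 5000.0
        assert normexp_correct(np.array([x]), self.P)[0] == pytest.approx(
            x - self.P.mu, rel=0.01
        )

    def test_offset_added_after_correction(self):
        x = np.array([1000.0])
        base = normexp_correct(x, self.P, 0.0)
        assert normexp_correct(x, self.P, 50.0)[0] == pytest.approx(base[0] + 50.0)


class TestMaLoess:
    def test_constant_bias_removed(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(5, 14, 500)
        log_g = a - 0.35  # M constant = 0.7
        log_r = a + 0.35
        m_norm, _ = ma_loess_normalize(log_r, log_g)
        assert np.abs(m_norm).max() < 1e-6

    def test_planted_smooth_bias_removed(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(4, 14, 2000))
        bias = 0.5 * np.sin(a / 2.0)
        m_norm, _ = ma_loess_normalize(a + bias / 2, a - bias / 2)
        assert np.abs(m_norm).max() < 0.05

    def test_near_fixed_point(self):
        # local regression is not a projection, so exact idempotency cannot
        # hold; a second application must change an already-normalized M by
        # far less than the bias the first pass removed
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(4, 14, 2000))
        bias = 0.5 * np.sin(a / 2.0)
        m1, _ = ma_loess_normalize(a + bias / 2, a - bias / 2)
        m2, _ = ma_loess_normalize(a + m1 / 2, a - m1 / 2)
        assert np.abs(m2 - m1).max() < 0.1 * np.abs(bias).max()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ma_loess_normalize(np.arange(5.0), np.arange(5.0))


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        for col in ("a", "b"):
            assert list(out[col]) == pytest.approx([2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_single_column_identity(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_ties_get_mean_of_spanned_quantiles(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = quantile_normalize(m)
        # reference = mean of sorted columns = [5.5, 10.5, 17.5]; the tied
        # pair in column a spans the two lowest quantiles -> both get 8.0
        assert list(out["a"]) == pytest.approx([8.0, 8.0, 17.5])

    def test_sorted_columns_identical_postcondition(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(200, 5)) * rng.gamma(2, size=5))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.sort(out[:, j]) == pytest.approx(ref, abs=1e-12)


class TestCollapseProbes:
    def test_replicates_collapsed_by_median(self):
        mat = pd.DataFrame({"A1": [1.0, 3.0]}, index=[0, 1])
        out = collapse_probes(mat, ["P1", "P1"], ["GENE_A", "GENE_A"], [500.0, 500.0])
        assert out.loc["GENE_A", "A1"] == pytest.approx(2.0)

    def test_highest_mean_cy5_probe_kept_per_symbol(self):
        mat = pd.DataFrame({"A1": [1.0, 9.0]})
        out = collapse_probes(mat, ["P1", "P2"], ["GENE_A", "GENE_A"], [500.0, 900.0])
        assert out.loc["GENE_A", "A1"] == pytest.approx(9.0)

    def test_unannotated_probes_filtered(self):
        mat = pd.DataFrame({"A1": [1.0, 2.0, 3.0]})
        out = collapse_probes(mat, ["P1", "P2", "P3"], ["GENE_A", "", None], [1, 1, 1])
        assert list(out.index) == ["GENE_A"]

    def test_gene_count_equals_distinct_annotated_symbols(self):
        rng = np.random.default_rng(0)
        n = 60
        ids = [f"P{i}" for i in range(n)]
        symbols = [f"GENE_{i % 20}" if i % 5 else "" for i in range(n)]
        mat = pd.DataFrame({"A1": rng.normal(size=n), "A2": rng.normal(size=n)})
        out = collapse_probes(mat, ids, symbols, rng.uniform(100, 1000, n))
        assert len(out) == len({s for s in symbols if s})

    def test_all_unannotated_rejected(self):
        mat = pd.DataFrame({"A1": [1.0]})
        with pytest.raises(ValidationError):
            collapse_probes(mat, ["P1"], [""], [1.0])


class TestPipeline:
    def test_null_batch_yields_near_zero_matrix(self):
        batch, truth = simulate_two_color(
            400, 4, replicate_fraction=0.1, unannotated_fraction=0.1,
            shared_channel_noise=True, seed=2,
        )
        expr = preprocess_pipeline(batch, RunConfig())
        assert np.abs(expr.to_numpy()).max() < 0.1
        assert len(expr) == int(truth["annotated_mask"].sum())

    def test_unannotated_probes_absent_from_output(self):
        batch, truth = simulate_two_color(300, 3, unannotated_fraction=0.1, seed=5)
        expr = preprocess_pipeline(batch, RunConfig())
        dropped = set(truth["gene_symbols"][~truth["annotated_mask"]])
        assert not dropped & set(expr.index)
        assert len(expr) == int(truth["annotated_mask"].sum())

    def test_deterministic_under_fixed_seed(self):
        batch1, _ = simulate_two_color(250, 3, replicate_fraction=0.05, seed=7)
        batch2, _ = simulate_two_color(250, 3, replicate_fraction=0.05, seed=7)
        pd.testing.assert_frame_equal(batch1, batch2)
        e1 = preprocess_pipeline(batch1, RunConfig())
        e2 = preprocess_pipeline(batch2, RunConfig())
        pd.testing.assert_frame_equal(e1, e2)

    def test_planted_two_fold_change_recovered(self):
        n_probes, ne = 4000, 40
        fc = np.zeros(n_probes)
        fc[:ne] = 1.0
        fc[ne : 2 * ne] = -1.0
        batch, _ = simulate_two_color(
            n_probes, 6,
            params_cy5=NormexpParams(200.0, 30.0, 5000.0),
            log2_fold_changes=fc,
            arrays_with_effect=np.array([True] * 3 + [False] * 3),
            baseline_ratio_sd=0.4, seed=1,
        )
        expr = preprocess_pipeline(batch, RunConfig())
        up = [g for g in (f"GENE{i:04d}" for i in range(1, ne + 1)) if g in expr.index]
        d = (
            expr.loc[up, ["A01", "A02", "A03"]].mean(axis=1)
            - expr.loc[up, ["A04", "A05", "A06"]].mean(axis=1)
        ).mean()
        assert 0.8 <= d <= 1.2
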