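"""RMA chain: background correction, quantile normalization, median polish."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import receptormine as rm
from receptormine.preprocess import median_polish

# ---------------------------------------------------------------------------
# independent oracles


def normexp_posterior_mean_quadrature(s: float, p: rm.NormexpParams) -> float:
    """E[X | S=s] by numerical integration of the convolution posterior."""

    def joint(x: float) -> float:
        return stats.expon.pdf(x, scale=p.alpha) * stats.norm.pdf(
            s - x, loc=p.mu, scale=p.sigma
        )

    # the integrand is a Gaussian bump near x = s - mu times an exponential:
    # integrate over a window wide enough to contain all its mass
    hi = max(s - p.mu, 0) + 15 * p.sigma
    peak = min(max(s - p.mu, 0), hi)
    num, _ = integrate.quad(lambda x: x * joint(x), 0, hi, limit=400, points=[peak])
    den, _ = integrate.quad(joint, 0, hi, limit=400, points=[peak])
    return num / den


def quantile_normalize_oracle(m: np.ndarray) -> np.ndarray:
    """Brute-force O(n^2): each entry gets the mean of the reference
    values at the sorted positions its (possibly tied) value occupies."""
    n, k = m.shape
    reference = np.sort(m, axis=0).mean(axis=1)
    out = np.empty_like(m, dtype=float)
    for j in range(k):
        col_sorted = np.sort(m[:, j])
        for i in range(n):
            positions = np.nonzero(col_sorted == m[i, j])[0]
            out[i, j] = reference[positions].mean()
    return out


# ---------------------------------------------------------------------------
# normexp


class TestNormexpCorrect:
    def test_symmetry_point_closed_form(self):
        p = rm.NormexpParams(mu=100, sigma=10, alpha=200)
        s = p.mu + p.sigma**2 / p.alpha  # m = 0
        got = rm.normexp_correct(np.array([s]), p)[0]
        assert got == pytest.approx(p.sigma * np.sqrt(2 / np.pi), rel=1e-12)

    def test_strictly_increasing_and_positive(self):
        p = rm.NormexpParams(mu=50, sigma=20, alpha=100)
        s = np.linspace(-400, 800, 500)
        out = rm.normexp_correct(s, p)
        assert np.all(out > 0)
        assert np.all(np.diff(out) > 0)

    def test_matches_quadrature(self):
        p = rm.NormexpParams(mu=100, sigma=10, alpha=200)
        grid = np.linspace(60, 600, 25)
        got = rm.normexp_correct(grid, p)
        expected = [normexp_posterior_mean_quadrature(s, p) for s in grid]
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_deep_negative_tail_stable(self):
        p = rm.NormexpParams(mu=0, sigma=1, alpha=1)
        out = rm.normexp_correct(np.array([-50.0, -500.0, -5000.0]), p)
        assert np.all(out > 0)
        assert np.all(np.diff(out) < 0)  # further below background -> smaller signal

    def test_non_finite_input_errors(self):
        p = rm.NormexpParams(mu=0, sigma=1, alpha=1)
        with pytest.raises(ValueError):
            rm.normexp_correct(np.array([1.0, np.nan]), p)


class TestNormexpEstimation:
    def test_recovery_from_convolution_draws(self):
        rng = np.random.default_rng(11)
        n = 50_000
        true = rm.NormexpParams(mu=100, sigma=20, alpha=500)
        s = rng.normal(true.mu, true.sigma, n) + rng.exponential(true.alpha, n)
        est = rm.estimate_normexp_params(s)
        assert est.mu == pytest.approx(true.mu, rel=0.15)
        assert est.sigma == pytest.approx(true.sigma, rel=0.15)
        assert est.alpha == pytest.approx(true.alpha, rel=0.15)

    def test_pure_background_regime(self):
        rng = np.random.default_rng(12)
        s = rng.normal(100, 20, 50_000)  # no signal at all
        est = rm.estimate_normexp_params(s)
        assert est.mu == pytest.approx(100, rel=0.05)
        assert est.alpha < 20  # signal mean collapses well below the background sd

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="constant"):
            rm.estimate_normexp_params(np.full(2000, 7.0))


# ---------------------------------------------------------------------------
# quantile normalization


class TestQuantileNormalize:
    def test_two_point_arithmetic(self):
        m = np.array([[1.0, 3.0], [2.0, 4.0]])
        np.testing.assert_allclose(
            rm.quantile_normalize(m), [[2.0, 2.0], [3.0, 3.0]]
        )

    def test_identical_columns_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        m = np.column_stack([col, col, col])
        np.testing.assert_allclose(rm.quantile_normalize(m), m)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 8, size=(20, 5)).astype(float)  # many ties
        np.testing.assert_allclose(
            rm.quantile_normalize(m), quantile_normalize_oracle(m), atol=1e-12
        )

    def test_columns_share_value_multiset_and_idempotence(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(40, 6))
        out = rm.quantile_normalize(m)
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
        np.testing.assert_allclose(rm.quantile_normalize(out), out, atol=1e-12)

    def test_missing_values_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="impute"):
            rm.quantile_normalize(m)


def test_log2_transform_values_and_errors():
    np.testing.assert_allclose(
        rm.log2_transform(np.array([[8.0, 1.0]])), [[3.0, 0.0]]
    )
    x = np.array([[0.3, 2.7]])
    np.testing.assert_allclose(np.exp2(rm.log2_transform(x)), x)
    with pytest.raises(ValueError):
        rm.log2_transform(np.array([[1.0, 0.0]]))


# ---------------------------------------------------------------------------
# median polish


class TestMedianPolish:
    def test_hand_run_additive_block(self):
        expr, resid = rm.median_polish_summarize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(expr, [2.0, 3.0])
        np.testing.assert_allclose(resid, 0, atol=1e-12)

    def test_constant_block(self):
        expr, resid = rm.median_polish_summarize(np.full((3, 4), 5.5))
        np.testing.assert_allclose(expr, 5.5)
        np.testing.assert_allclose(resid, 0)

    def test_single_probe_passthrough(self):
        row = np.array([1.0, 4.0, 2.0])
        expr, resid = rm.median_polish_summarize(row)
        np.testing.assert_array_equal(expr, row)
        np.testing.assert_array_equal(resid, 0)

    def test_random_block_residual_medians_near_zero(self):
        rng = np.random.default_rng(5)
        block = rng.normal(size=(5, 4))
        _, resid = rm.median_polish_summarize(block, tol=1e-9, max_iter=50)
        assert np.abs(np.median(resid, axis=0)).max() < 1e-6
        assert np.abs(np.median(resid, axis=1)).max() < 1e-6

    @settings(deadline=None, max_examples=40)
    @given(
        nr=st.integers(2, 20),
        nc=st.integers(2, 20),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_exactly_additive_matrix_zero_residuals(self, nr, nc, seed):
        rng = np.random.default_rng(seed)
        r = rng.normal(size=nr)
        c = rng.normal(size=nc)
        block = r[:, None] + c[None, :]
        overall, row_eff, col_eff, resid = median_polish(block, tol=1e-12, max_iter=50)
        np.testing.assert_allclose(resid, 0, atol=1e-9)
        np.testing.assert_allclose(
            overall + col_eff, np.median(r) + c, atol=1e-9
        )


# ---------------------------------------------------------------------------
# full chain + gene collapse


class TestRMA:
    def test_planted_effect_recovered(self, default_sim):
        experiment, truth, _ = default_sim
        probesets = rm.rma(experiment)
        genes = rm.collapse_to_genes(probesets, experiment.chip)
        idx = {g: i for i, g in enumerate(genes.row_ids)}
        cats = np.array([s.category for s in genes.samples])
        a = genes.values[:, cats == truth.category_names[0]].mean(axis=1)
        b = genes.values[:, cats == truth.category_names[-1]].mean(axis=1)
        k = truth.category_names.index(truth.category_names[-1])
        for gene in truth.de_genes:
            i = truth.gene_ids.index(gene)
            planted = truth.theta[i, k] - truth.theta[i, 0]
            observed = b[idx[gene]] - a[idx[gene]]
            assert observed == pytest.approx(planted, abs=0.5)

    def test_identical_columns_stay_identical(self, small_sim):
        experiment, _, _ = small_sim
        two = rm.ProbeExperiment(
            np.column_stack([experiment.intensities[:, 0]] * 2),
            list(experiment.probe_ids),
            [
                rm.SampleMeta("dup1", "X", "GPL1"),
                rm.SampleMeta("dup2", "X", "GPL1"),
            ],
            experiment.chip,
        )
        out = rm.rma(two)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], atol=1e-9)

    def test_sample_permutation_equivariance(self, small_sim):
        experiment, _, _ = small_sim
        out = rm.rma(experiment)
        perm = np.arange(len(experiment.samples))[::-1]
        shuffled = rm.ProbeExperiment(
            experiment.intensities[:, perm],
            list(experiment.probe_ids),
            [experiment.samples[j] for j in perm],
            experiment.chip,
        )
        out2 = rm.rma(shuffled)
        np.testing.assert_allclose(out2.values, out.values[:, perm], atol=1e-9)

    def test_probe_order_within_probeset_irrelevant(self, small_sim):
        experiment, _, _ = small_sim
        out = rm.rma(experiment)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(experiment.probe_ids))
        shuffled = rm.ProbeExperiment(
            experiment.intensities[perm, :],
            [experiment.probe_ids[i] for i in perm],
            list(experiment.samples),
            experiment.chip,
        )
        out2 = rm.rma(shuffled)
        assert out2.row_ids == out.row_ids
        np.testing.assert_allclose(out2.values, out.values, atol=1e-9)


class TestCollapseToGenes:
    def _matrix(self, values, probesets):
        samples = [rm.SampleMeta(f"s{j}", "X", "GPL1") for j in range(values.shape[1])]
        return rm.ExpressionMatrix(values, probesets, samples, level="probeset")

    def test_single_probeset_passthrough_and_mean(self):
        chip = rm.ChipDefinition(
            {}, {"ps1": "GeneA", "ps2": "GeneB", "ps3": "GeneB"}
        )
        m = self._matrix(
            np.array([[1.0, 2.0], [4.0, 4.0], [6.0, 6.0]]), ["ps1", "ps2", "ps3"]
        )
        out = rm.collapse_to_genes(m, chip)
        assert out.row_ids == ["GeneA", "GeneB"]
        np.testing.assert_allclose(out.values, [[1, 2], [5, 5]])
        assert out.level == "gene"

    def test_unannotated_probesets_dropped(self):
        chip = rm.ChipDefinition({}, {"ps1": "GeneA", "ps2": ""})
        m = self._matrix(np.ones((2, 2)), ["ps1", "ps2"])
        out = rm.collapse_to_genes(m, chip)
        assert out.row_ids == ["GeneA"]

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i % 7}" for i in range(25)]
        chip = rm.ChipDefinition({}, {f"ps{i}": genes[i] for i in range(25)})
        values = rng.normal(size=(25, 4))
        m = self._matrix(values, [f"ps{i}" for i in range(25)])
        out = rm.collapse_to_genes(m, chip)
        import pandas as pd

        expected = pd.DataFrame(values).groupby(np.array(genes)).mean()
        np.testing.assert_allclose(out.values, expected.to_numpy())
        assert out.row_ids == list(expected.index)
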