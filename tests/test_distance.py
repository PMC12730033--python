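"""Divergence matrices: standardization, pooled covariance, D2, Euclidean."""

import numpy as np
import pandas as pd
import pytest

from phenodiv import (
    anova_crd,
    mahalanobis_d2,
    pooled_residual_covariance,
    standardize,
    standardized_euclidean,
)
from conftest import random_means


class TestStandardize:
    def test_columns_become_zero_mean_unit_variance(self, rng):
        z = standardize(random_means(rng, 12, 4))
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.var(ddof=1), 1.0, atol=1e-12)

    def test_already_standardized_input_unchanged(self, rng):
        z = standardize(random_means(rng, 30, 3))
        assert np.allclose(standardize(z).to_numpy(), z.to_numpy(), atol=1e-12)

    def test_constant_column_rejected(self, rng):
        means = random_means(rng, 5, 2)
        means["t0"] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(means)


class TestPooledCovariance:
    def test_diagonal_equals_univariate_qmr(self, small_table):
        cov = pooled_residual_covariance(small_table)
        for i, trait in enumerate(cov.traits):
            qmr = anova_crd(small_table, trait).QMr
            assert cov.matrix[i, i] == pytest.approx(qmr, rel=1e-10)

    def test_df_matches_balanced_design(self, small_table):
        cov = pooled_residual_covariance(small_table)
        assert cov.df_r == 6 * (3 - 1)

    def test_psd(self, trial_table):
        cov = pooled_residual_covariance(trial_table)
        eig = np.linalg.eigvalsh(cov.matrix)
        assert eig.min() > -1e-8 * max(1.0, eig.max())


class TestMahalanobisD2:
    def test_identity_covariance_reduces_to_squared_euclidean(self, rng):
        means = random_means(rng, 8, 3)
        d2 = mahalanobis_d2(means, np.eye(3))
        x = means.to_numpy()
        for i in range(8):
            for j in range(8):
                expected = ((x[i] - x[j]) ** 2).sum()
                assert d2.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_two_genotype_one_trait_closed_form(self):
        means = pd.DataFrame({"t": [1.0, 3.0]}, index=["a", "b"])
        d2 = mahalanobis_d2(means, np.array([[4.0]]))
        assert d2[("a", "b")] == pytest.approx(1.0)

    def test_invariance_under_nonsingular_trait_recoding(self, rng):
        """D2 is unchanged by any nonsingular linear recoding of traits."""
        means = random_means(rng, 6, 4)
        w = np.cov(rng.normal(size=(40, 4)), rowvar=False)
        d2 = mahalanobis_d2(means, w)
        for _ in range(10):
            a = rng.normal(size=(4, 4))
            while abs(np.linalg.det(a)) < 1e-3:
                a = rng.normal(size=(4, 4))
            recoded = pd.DataFrame(
                means.to_numpy() @ a.T, index=means.index, columns=means.columns
            )
            d2_rec = mahalanobis_d2(recoded, a @ w @ a.T)
            assert np.allclose(d2_rec.values, d2.values, rtol=1e-8, atol=1e-8)

    def test_singular_covariance_falls_back_to_pseudo_inverse(self, rng):
        means = random_means(rng, 5, 2)
        w = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank 1
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            d2 = mahalanobis_d2(means, w)
        assert np.all(d2.values >= 0)

    def test_permuting_genotypes_permutes_matrix(self, rng):
        means = random_means(rng, 6, 3)
        d2 = mahalanobis_d2(means, np.eye(3))
        perm = means.iloc[::-1]
        d2p = mahalanobis_d2(perm, np.eye(3))
        assert np.allclose(d2p.values, d2.values[::-1, ::-1])


class TestStandardizedEuclidean:
    def test_identical_rows_have_zero_distance(self):
        means = pd.DataFrame(
            {"t1": [1.0, 1.0, 5.0], "t2": [2.0, 2.0, 0.0]}, index=["a", "b", "c"]
        )
        d = standardized_euclidean(means)
        assert d[("a", "b")] == pytest.approx(0.0, abs=1e-12)

    def test_single_trait_reduces_to_abs_z_difference(self, rng):
        means = random_means(rng, 6, 1)
        z = standardize(means)["t0"]
        d = standardized_euclidean(means)
        for i, a in enumerate(means.index):
            for j, b in enumerate(means.index):
                assert d.values[i, j] == pytest.approx(abs(z[a] - z[b]), abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        means = random_means(rng, 5, 3)
        z = standardize(means).to_numpy()
        d = standardized_euclidean(means)
        dm = standardized_euclidean(means, mean_variant=True)
        for i in range(5):
            for j in range(5):
                sq = ((z[i] - z[j]) ** 2).sum()
                assert d.values[i, j] == pytest.approx(np.sqrt(sq), abs=1e-12)
                assert dm.values[i, j] == pytest.approx(np.sqrt(sq / 3), abs=1e-12)

    def test_triangle_inequality(self, rng):
        means = random_means(rng, 10, 4)
        d = standardized_euclidean(means).values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
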