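import numpy as np
import pytest
from scipy import stats

import cpo
from cpo import DietMatrix, ValidationError
from cpo.cca import pseudo_F, unconstrained_ca_eigenvalues

from conftest import random_count_matrix

# Values computed independently with vegan::cca (R) on the small_diet /
# small_design fixture; frozen to 12 significant digits.
VEGAN_TOTAL = 0.683325924606091
VEGAN_EIG = [0.348946255922712, 0.255202953618655]
VEGAN_CONSTRAINED = 0.604149209541367
VEGAN_PARTIAL_COND = 0.0725680459071941
VEGAN_PARTIAL_EIG = [0.334665344091358, 0.249169590602644]
VEGAN_PARTIAL_CONSTRAINED = 0.583834934694002
VEGAN_PARTIAL_RESID = 0.0269229440048945
VEGAN_F = 11.4455848991871
VEGAN_PARTIAL_F = 21.685404634347


class TestChiSquareResiduals:
    def test_independence_table_has_zero_inertia(self):
        chi = cpo.chi_square_residuals(np.array([[1.0, 1], [1, 1]]))
        assert chi.total_inertia == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(chi.Q, 0.0, atol=1e-15)

    def test_diagonal_table(self):
        chi = cpo.chi_square_residuals(np.array([[2.0, 0], [0, 2]]))
        assert chi.total_inertia == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(chi.Q, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_weights_are_simplex(self):
        rng = np.random.default_rng(1)
        chi = cpo.chi_square_residuals(random_count_matrix(rng))
        assert chi.row_weights.sum() == pytest.approx(1.0)
        assert chi.col_weights.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_total_inertia_is_pearson_chisq_over_total(self, seed):
        """Independent oracle: scipy's Pearson chi-square of the table."""
        rng = np.random.default_rng(seed)
        counts = random_count_matrix(rng)
        chi = cpo.chi_square_residuals(counts)
        expected = stats.chi2_contingency(counts, correction=False)[0] / counts.sum()
        assert chi.total_inertia == pytest.approx(expected, abs=1e-9)

    def test_row_weighted_column_sums_vanish(self):
        rng = np.random.default_rng(2)
        chi = cpo.chi_square_residuals(random_count_matrix(rng))
        sums = np.sqrt(chi.row_weights) @ chi.Q
        np.testing.assert_allclose(sums, 0.0, atol=1e-12)


class TestWeightedCenter:
    def test_constant_column_becomes_zero(self):
        r = np.full(4, 0.25)
        out = cpo.weighted_center(np.ones((4, 1)), r)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_weighted_means_vanish(self):
        rng = np.random.default_rng(3)
        r = rng.dirichlet(np.ones(5))
        M = rng.normal(size=(5, 3))
        out = cpo.weighted_center(M, r)
        # columns are weighted-centered then sqrt(r)-scaled, so the
        # sqrt(r)-weighted sums vanish
        np.testing.assert_allclose(np.sqrt(r) @ out, 0.0, atol=1e-12)


class TestPartialOut:
    def test_empty_covariates_identity(self):
        rng = np.random.default_rng(4)
        Q = rng.normal(size=(5, 3))
        Q_res, cov = cpo.partial_out(Q, np.zeros((5, 0)))
        np.testing.assert_array_equal(Q_res, Q)
        assert cov == 0.0

    def test_saturated_projection_removes_everything(self, small_diet):
        chi = cpo.chi_square_residuals(small_diet)
        rng = np.random.default_rng(5)
        Z = cpo.weighted_center(rng.normal(size=(6, 5)), chi.row_weights)
        Q_res, cov = cpo.partial_out(chi.Q, Z)
        # 5 independent columns span the whole weighted-centered row space
        np.testing.assert_allclose(Q_res, 0.0, atol=1e-9)
        assert cov == pytest.approx(chi.total_inertia, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_pythagoras(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.normal(size=(8, 4))
        Z = rng.normal(size=(8, 2))
        Q_res, cov = cpo.partial_out(Q, Z)
        assert (Q_res ** 2).sum() + cov == pytest.approx((Q ** 2).sum(), abs=1e-9)


class TestConstrainedOrdinationAgainstVegan:
    def test_plain_cca_matches(self, small_diet, small_design):
        X, _ = small_design
        res = cpo.constrained_ordination(small_diet, X)
        assert res.total_inertia == pytest.approx(VEGAN_TOTAL, abs=1e-12)
        np.testing.assert_allclose(res.eigenvalues, VEGAN_EIG, atol=1e-12)
        assert res.constrained_inertia == pytest.approx(VEGAN_CONSTRAINED, abs=1e-12)
        assert pseudo_F(res) == pytest.approx(VEGAN_F, abs=1e-10)

    def test_partial_cca_matches(self, small_diet, small_design):
        X, z = small_design
        res = cpo.constrained_ordination(small_diet, X, z)
        assert res.covariate_inertia == pytest.approx(VEGAN_PARTIAL_COND, abs=1e-12)
        np.testing.assert_allclose(res.eigenvalues, VEGAN_PARTIAL_EIG, atol=1e-12)
        assert res.constrained_inertia == pytest.approx(VEGAN_PARTIAL_CONSTRAINED, abs=1e-12)
        assert res.residual_inertia == pytest.approx(VEGAN_PARTIAL_RESID, abs=1e-12)
        assert pseudo_F(res) == pytest.approx(VEGAN_PARTIAL_F, abs=1e-10)


class TestConstrainedOrdinationProperties:
    def test_two_point_separation(self):
        Y = np.array([[2.0, 0], [0, 2], [1, 1]])
        # constraint separating the two extreme rows from the mixed one
        res = cpo.constrained_ordination(Y, np.array([[1.0], [0], [0]]))
        assert res.constrained_inertia + res.residual_inertia == \
            pytest.approx(res.total_inertia, abs=1e-12)

    def test_fully_separating_constraint_captures_all(self):
        Y = np.array([[2.0, 0], [0, 2], [2, 0]])
        # rows 0 and 2 are identical profiles; the indicator of row 1
        # separates the two distinct profiles, so nothing is left over
        res = cpo.constrained_ordination(Y, np.array([[0.0], [1], [0]]))
        assert res.constrained_inertia == pytest.approx(res.total_inertia, abs=1e-12)
        assert res.residual_inertia == pytest.approx(0.0, abs=1e-12)

    def test_constant_constraint_is_error(self, small_diet):
        with pytest.raises(ValidationError, match="no testable constraint"):
            cpo.constrained_ordination(small_diet, np.ones((6, 1)))

    def test_constraints_equal_covariates_is_error(self, small_diet, small_design):
        X, _ = small_design
        with pytest.raises(ValidationError, match="no testable constraint"):
            cpo.constrained_ordination(small_diet, X, X)

    @pytest.mark.parametrize("seed", range(5))
    def test_inertia_conservation(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_count_matrix(rng, min_n=6, max_n=12)
        n = counts.shape[0]
        X = (rng.random((n, 3)) < 0.5).astype(float)
        Z = rng.normal(size=(n, 2))
        try:
            res = cpo.constrained_ordination(counts, X, Z)
        except ValidationError:
            return
        assert res.covariate_inertia + res.constrained_inertia + res.residual_inertia \
            == pytest.approx(res.total_inertia, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_constraints_reproduce_plain_ca(self, seed):
        rng = np.random.default_rng(100 + seed)
        counts = random_count_matrix(rng, min_n=5, max_n=9, min_m=3)
        n = counts.shape[0]
        X = rng.normal(size=(n, n - 1))  # full rank after weighted centering
        res = cpo.constrained_ordination(counts, X)
        np.testing.assert_allclose(
            res.eigenvalues, unconstrained_ca_eigenvalues(counts), atol=1e-9)

    def test_row_permutation_invariance(self, small_diet, small_design):
        X, z = small_design
        res = cpo.constrained_ordination(small_diet, X, z)
        perm = np.array([3, 0, 5, 1, 4, 2])
        res_p = cpo.constrained_ordination(small_diet.counts[perm], X[perm], z[perm])
        np.testing.assert_allclose(res_p.eigenvalues, res.eigenvalues, atol=1e-12)
        assert res_p.covariate_inertia == pytest.approx(res.covariate_inertia, abs=1e-12)
        assert res_p.residual_inertia == pytest.approx(res.residual_inertia, abs=1e-12)

    def test_adding_constraint_column_is_monotone(self, small_diet):
        rng = np.random.default_rng(7)
        X1 = (rng.random((6, 2)) < 0.5).astype(float)
        extra = (rng.random((6, 1)) < 0.5).astype(float)
        r1 = cpo.constrained_ordination(small_diet, X1)
        r2 = cpo.constrained_ordination(small_diet, np.hstack([X1, extra]))
        assert r2.constrained_inertia >= r1.constrained_inertia - 1e-12


class TestPseudoF:
    def test_arithmetic_from_definition(self):
        res = cpo.OrdinationResult(
            eigenvalues=np.array([0.5]), total_inertia=1.0,
            constrained_inertia=0.5, covariate_inertia=0.0,
            residual_inertia=0.5, rank_constraints=1, rank_covariates=0, n_rows=4)
        assert pseudo_F(res, "global") == pytest.approx(2.0)

    def test_zero_residual_flags_infinity(self):
        res = cpo.OrdinationResult(
            eigenvalues=np.array([1.0]), total_inertia=1.0,
            constrained_inertia=1.0, covariate_inertia=0.0,
            residual_inertia=0.0, rank_constraints=1, rank_covariates=0, n_rows=4)
        with pytest.warns(UserWarning, match="infinite"):
            assert pseudo_F(res, "global") == np.inf

    def test_no_residual_df_is_error(self):
        res = cpo.OrdinationResult(
            eigenvalues=np.array([0.5]), total_inertia=1.0,
            constrained_inertia=0.5, covariate_inertia=0.0,
            residual_inertia=0.5, rank_constraints=3, rank_covariates=0, n_rows=4)
        with pytest.raises(ValidationError, match="degrees of freedom"):
            pseudo_F(res, "global")


class TestAxisScores:
    def test_scale_invariance_of_scores(self, small_diet, small_design):
        X, _ = small_design
        res1 = cpo.constrained_ordination(small_diet, X)
        res2 = cpo.constrained_ordination(small_diet.counts * 2, X)
        np.testing.assert_allclose(np.abs(res2.row_scores), np.abs(res1.row_scores),
                                   atol=1e-10)
        np.testing.assert_allclose(np.abs(res2.column_scores),
                                   np.abs(res1.column_scores), atol=1e-10)

    def test_weighted_averaging_identity(self):
        """Column principal coordinates are the column-weighted averages of
        the row standard coordinates (classic CA transition formula),
        checked through the symmetric scores on a 3x3 table."""
        counts = np.array([[4.0, 1, 0], [1, 3, 2], [0, 2, 5]])
        n = counts.shape[0]
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n, n - 1))  # full rank: unconstrained CA
        res = cpo.constrained_ordination(counts, X)
        chi = cpo.chi_square_residuals(counts)
        P = counts / counts.sum()
        s = np.sqrt(res.eigenvalues)
        row_standard = res.row_scores / np.sqrt(s)     # U / sqrt(r)
        col_principal = res.column_scores * np.sqrt(s)  # (V / sqrt(c)) * s
        wa = (P.T / chi.col_weights[:, None]) @ row_standard
        np.testing.assert_allclose(wa, col_principal, atol=1e-10)

    def test_single_positive_eigenvalue_gives_single_axis(self):
        Y = np.array([[2.0, 0], [0, 2], [1, 1]])
        res = cpo.constrained_ordination(Y, np.array([[1.0], [0], [0]]))
        assert res.row_scores.shape[1] == 1

    def test_axis_percent_conventions_both_reported(self, small_diet, small_design):
        X, _ = small_design
        res = cpo.constrained_ordination(small_diet, X)
        assert res.axis_percent_of_constrained.sum() == pytest.approx(100.0)
        assert res.axis_percent_of_total.sum() == \
            pytest.approx(100.0 * res.constrained_inertia / res.total_inertia)

    def test_biplot_scores_bounded_by_one(self, small_diet, small_design):
        X, _ = small_design
        res = cpo.constrained_ordination(small_diet, X)
        assert np.all(np.abs(res.biplot_scores) <= 1 + 1e-9)
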