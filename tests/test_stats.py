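"""Null model, burden and SKAT tests, mixture tails, influence, FDR."""

import numpy as np
import pytest
from scipy import stats as sps

from binkat.binning import Bin
from binkat.stats import (
    bh_fdr,
    burden_score,
    burden_test,
    fit_null_model,
    leave_one_out,
    mixture_pvalue,
    skat_lambdas,
    skat_permutation_pvalue,
    skat_q,
    skat_test,
    wilcoxon_burden_test,
)
from binkat.variant_io import GenotypeMatrix

from simhelpers import covariate_design, random_rare_bin


def _geno(dosage):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(dosage, np.zeros_like(dosage, dtype=bool), [])


def _bin(m, weights=None):
    return Bin("f", "gene", np.arange(m), np.ones(m) if weights is None else np.asarray(weights, float))


class TestNullModel:
    def test_intercept_only_closed_form(self):
        null = fit_null_model([1.0, 2.0, 3.0], np.ones((3, 1)))
        np.testing.assert_allclose(null.residuals, [-1.0, 0.0, 1.0], atol=1e-12)
        assert null.sigma2 == pytest.approx(1.0)

    def test_residuals_orthogonal_to_design(self, rng):
        X, y = covariate_design(100, 4, rng, effects=[1.0, 0.5, -0.3, 0.2, 0.1])
        null = fit_null_model(y, X)
        assert np.abs(X.T @ null.residuals).max() < 1e-8 * np.abs(y).sum()

    def test_phenotype_in_design_span_fatal(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="residual variance"):
            fit_null_model(X[:, 1] * 2 + 3, X)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="columns: \\[2\\]"):
            fit_null_model(np.random.default_rng(0).standard_normal(10), X)

    def test_coefficient_recovery_within_3se(self, rng):
        beta = np.array([0.5, 1.0, -0.8, 0.3])
        X = np.column_stack([np.ones(500), rng.standard_normal((500, 3))])
        y = X @ beta + rng.standard_normal(500)
        null = fit_null_model(y, X)
        bhat = np.linalg.lstsq(X, y - null.residuals, rcond=None)[0]
        se = np.sqrt(null.sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(bhat - beta) < 3 * se)

    def test_projection_matches_explicit_matrix(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        null = fit_null_model(rng.standard_normal(30), X)
        M = np.eye(30) - X @ np.linalg.inv(X.T @ X) @ X.T
        v = rng.standard_normal(30)
        np.testing.assert_allclose(null.project(v), M @ v, atol=1e-10)


class TestBurden:
    def test_score_direct_sum(self):
        geno = _geno([[1.0, 1.0]])
        assert burden_score(_bin(2, [1.0, 2.0]), geno).tolist() == [3.0]

    def test_score_all_zero(self):
        geno = _geno(np.zeros((4, 3)))
        assert burden_score(_bin(3), geno).tolist() == [0.0] * 4

    def test_score_equals_row_sums_with_unit_weights(self, rng):
        dosage = rng.integers(0, 3, size=(20, 6)).astype(float)
        np.testing.assert_allclose(
            burden_score(_bin(6), _geno(dosage)), dosage.sum(axis=1)
        )

    def test_constant_score_flagged_uninformative(self, rng):
        X, y = covariate_design(50, 2, rng)
        geno = _geno(np.ones((50, 3)))
        res = burden_test(_bin(3), geno, y, X)
        assert res.p_value == 1.0 and res.flag == "uninformative-bin"

    def test_detects_strong_signal(self, rng):
        b, geno, G = random_rare_bin(500, 10, rng)
        X = np.column_stack([np.ones(500), rng.standard_normal((500, 2))])
        s = burden_score(b, geno)
        y = 0.5 * s + rng.standard_normal(500)
        res = burden_test(b, geno, y, X)
        assert res.p_value < 1e-4
        assert res.test == "burden" and res.p_method == "exact-t"

    def test_matches_two_sided_t_oracle(self, rng):
        b, geno, G = random_rare_bin(200, 8, rng)
        X, y = covariate_design(200, 3, rng)
        res = burden_test(b, geno, y, X)
        # explicit OLS via normal equations
        D = np.column_stack([X, burden_score(b, geno)])
        coef, rss_arr, *_ = np.linalg.lstsq(D, y, rcond=None)
        dof = 200 - D.shape[1]
        resid = y - D @ coef
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.linalg.inv(D.T @ D)[-1, -1])
        t = coef[-1] / se
        assert res.statistic == pytest.approx(t, rel=1e-8)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), dof), rel=1e-8)


class TestWilcoxon:
    def test_exact_enumeration_small_groups(self):
        geno = _geno(np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]))
        res = wilcoxon_burden_test(_bin(1), geno, [0, 0, 0, 1, 1, 1])
        assert res.p_value == pytest.approx(0.1)
        assert res.p_method == "exact-enum"
        assert res.statistic == pytest.approx(4 + 5 + 6)  # rank-sum of group 1

    def test_identical_multisets_near_one(self):
        geno = _geno(np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]]))
        res = wilcoxon_burden_test(_bin(1), geno, [0, 0, 0, 1, 1, 1])
        assert res.p_value > 0.9

    def test_empty_group_fatal(self):
        geno = _geno(np.ones((3, 1)))
        with pytest.raises(ValueError):
            wilcoxon_burden_test(_bin(1), geno, [1, 1, 1])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(2000):
            scores = rng.standard_normal((120, 1))
            labels = rng.permuted(np.repeat([0, 1], 60))
            res = wilcoxon_burden_test(_bin(1), _geno(scores), labels)
            pvals.append(res.p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestSkatCore:
    def test_q_closed_form(self):
        null = fit_null_model([1.0, -1.0], np.ones((2, 1)))
        np.testing.assert_allclose(null.residuals, [1.0, -1.0])
        assert skat_q(null, _bin(2), _geno(np.eye(2))) == pytest.approx(2.0)

    def test_q_zero_for_zero_genotypes(self):
        null = fit_null_model([1.0, -1.0, 0.5], np.ones((3, 1)))
        assert skat_q(null, _bin(2), _geno(np.zeros((3, 2)))) == 0.0

    def test_q_matches_dense_quadratic_form(self, rng):
        X, y = covariate_design(30, 2, rng)
        null = fit_null_model(y, X)
        Z = rng.standard_normal((30, 5))
        w = rng.uniform(0.5, 2.0, 5)
        q = skat_q(null, _bin(5, w), _geno(Z))
        K = (Z * w) @ (Z * w).T
        assert q == pytest.approx(null.residuals @ K @ null.residuals, rel=1e-10)

    def test_lambda_single_column_closed_form(self):
        y = np.array([0.0, np.sqrt(3), 0.0, np.sqrt(3)])
        null = fit_null_model(y, np.ones((4, 1)))
        assert null.sigma2 == pytest.approx(1.0)
        z = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        lam = skat_lambdas(null, _bin(1), _geno(z))
        np.testing.assert_allclose(lam, [4.0], rtol=1e-10)

    def test_projection_annihilates_design_column(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        null = fit_null_model(rng.standard_normal(20), X)
        res = skat_test(null, _bin(1), _geno(X[:, [1]]))
        assert res.p_value == 1.0 and res.flag == "uninformative-bin"

    def test_trace_identity(self, rng):
        b, geno, G = random_rare_bin(80, 12, rng)
        X, y = covariate_design(80, 3, rng)
        null = fit_null_model(y, X)
        lam = skat_lambdas(null, b, geno)
        Z = geno.dosage[:, b.variant_indices] * b.weights
        MZ = null.project(Z)
        assert lam.sum() == pytest.approx(null.sigma2 * np.trace(Z.T @ MZ), rel=1e-10)

    def test_q_invariant_to_design_span_shift(self, rng):
        b, geno, G = random_rare_bin(100, 8, rng)
        X, y = covariate_design(100, 3, rng)
        shift = X @ rng.standard_normal(4)
        q1 = skat_q(fit_null_model(y, X), b, geno)
        q2 = skat_q(fit_null_model(y + shift, X), b, geno)
        assert q2 == pytest.approx(q1, rel=1e-9)


class TestMixturePvalue:
    @pytest.mark.parametrize(
        "q,lam,expected",
        [
            (3.841459, [1.0], 0.05),
            (5.991465, [1.0, 1.0], 0.05),
            (7.682918, [2.0], 0.05),
        ],
    )
    def test_chi_square_closed_forms(self, q, lam, expected):
        p, method = mixture_pvalue(q, lam)
        assert p == pytest.approx(expected, abs=1e-6)
        assert method == "davies"

    def test_matches_monte_carlo_tail(self, rng):
        lam = np.array([1.0, 0.5, 0.1])
        p, _ = mixture_pvalue(5.0, lam)
        draws = (rng.chisquare(1, size=(1_000_000, 3)) * lam).sum(axis=1)
        mc = (draws > 5.0).mean()
        assert abs(p - mc) < 3 * np.sqrt(mc * (1 - mc) / 1e6)

    def test_weight_scaling_leaves_p_unchanged(self, rng):
        lam = rng.uniform(0.1, 2.0, 8)
        q = lam.sum() * 1.7
        p1, _ = mixture_pvalue(q, lam)
        p2, _ = mixture_pvalue(q * 5.5**2, lam * 5.5**2)
        assert abs(p1 - p2) < 1e-9

    @pytest.mark.parametrize("bad", [[], [0.0, 1.0], [-1.0]])
    def test_invalid_lambdas_fatal(self, bad):
        with pytest.raises(ValueError):
            mixture_pvalue(1.0, bad)

    def test_liu_moment_match_reasonable(self):
        p_exact, _ = mixture_pvalue(10.0, [1.0, 0.8, 0.5, 0.2], method="auto")
        p_liu, method = mixture_pvalue(10.0, [1.0, 0.8, 0.5, 0.2], method="liu")
        assert method == "liu"
        assert p_liu == pytest.approx(p_exact, rel=0.1)


class TestSkatTest:
    def test_single_variant_degenerates_to_score_chi2(self, rng):
        b, geno, G = random_rare_bin(150, 1, rng, maf_range=(0.02, 0.049))
        y = rng.standard_normal(150)
        null = fit_null_model(y, np.ones((150, 1)))
        res = skat_test(null, b, geno)
        z = geno.dosage[:, b.variant_indices] * b.weights
        u = float(z[:, 0] @ null.residuals)
        lam = null.sigma2 * float(z[:, 0] @ null.project(z[:, 0]))
        p_oracle = sps.chi2.sf(u**2 / lam, 1)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-8)

    def test_scaling_all_weights_preserves_p(self, rng):
        b, geno, G = random_rare_bin(120, 8, rng)
        X, y = covariate_design(120, 2, rng)
        null = fit_null_model(y, X)
        p1 = skat_test(null, b, geno).p_value
        b2 = Bin(b.feature_id, b.level, b.variant_indices, b.weights * 3.7)
        p2 = skat_test(null, b2, geno).p_value
        assert abs(p1 - p2) < 1e-9

    def test_agrees_with_residual_permutation_small_bin(self, rng):
        # plug-in mixture tail vs permutation reference in the small-bin
        # regime where the plug-in approximation error is negligible
        b, geno, G = random_rare_bin(200, 5, rng, maf_range=(0.01, 0.049))
        y = rng.standard_normal(200)
        null = fit_null_model(y, np.ones((200, 1)))
        pa = skat_test(null, b, geno).p_value
        pp = skat_permutation_pvalue(null, b, geno, 50_000, rng)
        se = np.sqrt(pp * (1 - pp) / 50_000)
        assert abs(pa - pp) < max(3 * se, 0.01)


class TestLeaveOneOut:
    def test_consistency_with_manual_subslicing(self, rng):
        b, geno, G = random_rare_bin(100, 6, rng)
        X, y = covariate_design(100, 2, rng)
        null = fit_null_model(y, X)
        rows = dict(leave_one_out(null, b, geno))
        for k in range(b.size):
            keep = np.ones(b.size, dtype=bool)
            keep[k] = False
            sub = Bin("f", "gene", b.variant_indices[keep], b.weights[keep])
            assert rows[str(b.variant_indices[k])] == pytest.approx(
                skat_test(null, sub, geno).p_value
            )

    def test_sorted_ascending_and_most_influential_last(self, rng):
        b, geno, G = random_rare_bin(300, 10, rng)
        j = 3
        y = 2.0 * G[:, j] + rng.standard_normal(300)
        null = fit_null_model(y, np.ones((300, 1)))
        rows = leave_one_out(null, b, geno)
        ps = [p for _, p in rows]
        assert ps == sorted(ps)
        assert rows[-1][0] == str(j)

    def test_size_one_fatal(self, rng):
        b, geno, G = random_rare_bin(50, 1, rng, maf_range=(0.02, 0.049))
        y = rng.standard_normal(50)
        null = fit_null_model(y, np.ones((50, 1)))
        with pytest.raises(ValueError):
            leave_one_out(null, b, geno)


def brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(m * p[order[k]] / (k + 1) for k in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.0266667, 0.8], rtol=1e-5)

    def test_single_pvalue(self):
        assert bh_fdr([0.5]).tolist() == [0.5]

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), rtol=1e-10)

    def test_q_dominates_p(self, rng):
        p = rng.uniform(1e-6, 1.0, 30)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1]])
    def test_out_of_range_fatal(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)
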