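import numpy as np
import pytest

import tagnet as tg
from tagnet.sem import (IdentificationError, MatrixDomainError,
                        SingularModelError, independence_chi2,
                        _fml_and_grad)
from tests.conftest import random_path_model, sample_cov


def brute_force_sigma(model, theta):
    """Independent oracle: explicit matrix construction via numpy only."""
    lam, phi = model.matrices(theta)
    q = len(model.nodes)
    B = np.linalg.inv(np.eye(q) - lam)
    return B @ phi @ B.T


def brute_force_fml(S, sigma):
    """Oracle discrepancy with log-dets from eigenvalues."""
    q = S.shape[0]
    ev_m = np.linalg.eigvalsh(sigma)
    ev_s = np.linalg.eigvalsh(S)
    return (np.sum(np.log(ev_m)) - np.sum(np.log(ev_s))
            + np.trace(np.linalg.inv(sigma) @ S) - q)


class TestImpliedCovariance:
    def test_empty_model_identity(self):
        m = tg.PathModel(nodes=["a", "b", "c"])
        sigma = tg.implied_covariance(m, np.ones(3))
        np.testing.assert_allclose(sigma, np.eye(3))

    def test_two_node_hand_value(self, two_node_model):
        sigma = tg.implied_covariance(two_node_model, np.array([0.5, 1, 1]))
        np.testing.assert_allclose(sigma, [[1, 0.5], [0.5, 1.25]])

    def test_unit_feedback_loop_singular(self):
        m = tg.PathModel(nodes=["a", "b"])
        m.add_edge("a", "b")
        m.add_edge("b", "a")
        with pytest.raises(SingularModelError):
            tg.implied_covariance(m, np.array([1.0, 1.0, 1.0, 1.0]))

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(2, 9))
        model, theta = random_path_model(rng, q)
        sigma = tg.implied_covariance(model, theta)
        np.testing.assert_allclose(sigma, brute_force_sigma(model, theta),
                                   atol=1e-8)


class TestMlDiscrepancy:
    def test_equal_matrices_zero(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert tg.ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        f = tg.ml_discrepancy(np.eye(2), np.diag([2.0, 1.0]))
        assert f == pytest.approx(np.log(2) + 1.5 - 2, abs=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(MatrixDomainError):
            tg.ml_discrepancy(np.eye(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    @pytest.mark.parametrize("seed", range(100))
    def test_positive_for_distinct_pd_pairs(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(2, 6))
        a = rng.normal(size=(q, q + 2))
        b = rng.normal(size=(q, q + 2))
        S = a @ a.T / (q + 2)
        sigma = b @ b.T / (q + 2)
        f = tg.ml_discrepancy(S, sigma)
        assert f > 0
        assert f == pytest.approx(brute_force_fml(S, sigma), abs=1e-8)


class TestFitModel:
    def test_two_node_recovery(self, two_node_model):
        S, _ = sample_cov(two_node_model, np.array([0.5, 1, 1]), 10_000, 3)
        fm = tg.fit_model(two_node_model, S, 10_000)
        assert abs(fm.theta["x1->x2"] - 0.5) < 0.05
        assert abs(fm.theta["var(x1)"] - 1.0) < 0.05
        assert abs(fm.theta["var(x2)"] - 1.0) < 0.05

    def test_saturated_model_chi2_zero(self):
        m = tg.PathModel(nodes=["a", "b", "c"])
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            m.add_error_covariance(*pair)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 3))
        S = np.cov(x, rowvar=False, ddof=1)
        fm = tg.fit_model(m, S, 100)
        assert fm.chi2 == pytest.approx(0.0, abs=1e-10)
        assert fm.df == 0
        np.testing.assert_allclose(fm.implied, S, atol=1e-10)

    def test_standard_errors_match_finite_difference_oracle(self,
                                                            two_node_model):
        S, _ = sample_cov(two_node_model, np.array([0.5, 1, 1]), 10_000, 3)
        n = 10_000
        fm = tg.fit_model(two_node_model, S, n)
        theta = fm.theta.to_numpy()
        # independent numerical Hessian of (n-1)/2 * F via function values
        m = len(theta)
        H = np.zeros((m, m))
        h = 1e-4

        def f(t):
            return _fml_and_grad(two_node_model, t, S)[0]

        f0 = f(theta)
        for i in range(m):
            for j in range(m):
                if i == j:
                    tp = theta.copy(); tp[i] += h
                    tm = theta.copy(); tm[i] -= h
                    H[i, i] = (f(tp) - 2 * f0 + f(tm)) / (h * h)
                    continue
                tpp = theta.copy(); tpp[i] += h; tpp[j] += h
                tpm = theta.copy(); tpm[i] += h; tpm[j] -= h
                tmp = theta.copy(); tmp[i] -= h; tmp[j] += h
                tmm = theta.copy(); tmm[i] -= h; tmm[j] -= h
                H[i, j] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * h * h)
        se_oracle = np.sqrt(np.diag(np.linalg.inv(H * (n - 1) / 2)))
        np.testing.assert_allclose(fm.se.to_numpy(), se_oracle, rtol=0.05)

    def test_chi2_invariant_to_node_reordering(self, chain_model):
        theta = np.array([0.6, 0.5, 1, 1, 1])
        S, df = sample_cov(chain_model, theta, 2000, 7)
        fm1 = tg.fit_model(chain_model, S, 2000)
        m2 = tg.PathModel(nodes=["x3", "x1", "x2"])
        m2.add_edge("x1", "x2")
        m2.add_edge("x2", "x3")
        perm = [2, 0, 1]
        S2 = S[np.ix_(perm, perm)]
        fm2 = tg.fit_model(m2, S2, 2000)
        assert fm1.chi2 == pytest.approx(fm2.chi2, abs=1e-6)

    def test_df_negative_raises(self):
        m = tg.PathModel(nodes=["a", "b"])
        m.add_edge("a", "b")
        m.add_edge("b", "a")
        m.add_error_covariance("a", "b")
        with pytest.raises(IdentificationError):
            tg.fit_model(m, np.eye(2) + 0.1, 100)

    def test_standardized_weight_scaling(self, two_node_model):
        """Standardized weights are invariant to rescaling a variable when
        S is recomputed accordingly."""
        S, _ = sample_cov(two_node_model, np.array([0.5, 1, 1]), 5000, 11)
        fm = tg.fit_model(two_node_model, S, 5000)
        D = np.diag([3.0, 0.5])
        fm2 = tg.fit_model(two_node_model.copy(), D @ S @ D, 5000)
        w1 = fm.standardized_weights()["standardized_weight"].to_numpy()
        w2 = fm2.standardized_weights()["standardized_weight"].to_numpy()
        np.testing.assert_allclose(w1, w2, atol=1e-6)


class TestFitIndices:
    def test_saturated_aic_16_variables(self):
        rep = tg.fit_indices(chi2=0.0, df=0, n=210, chi2_indep=5000.0,
                             df_indep=120, n_free_params=136, q=16)
        assert rep.aic == 272
        assert rep.saturated["AIC"] == 272

    def test_saturated_aic_9_variables(self):
        rep = tg.fit_indices(chi2=0.0, df=0, n=210, chi2_indep=600.0,
                             df_indep=36, n_free_params=45, q=9)
        assert rep.aic == 90

    def test_independence_scored_against_itself_cfi_zero(self):
        rep = tg.fit_indices(chi2=700.0, df=36, n=210, chi2_indep=700.0,
                             df_indep=36, n_free_params=9, q=9)
        assert rep.cfi == 0.0

    def test_rmsea_hand_value(self):
        rep = tg.fit_indices(chi2=50.0, df=25, n=210, chi2_indep=500.0,
                             df_indep=36, n_free_params=20, q=9)
        assert rep.rmsea == pytest.approx(np.sqrt(25 / (25 * 209)), abs=1e-9)

    def test_df_zero_undefined_markers(self):
        rep = tg.fit_indices(chi2=0.0, df=0, n=210, chi2_indep=100.0,
                             df_indep=10, n_free_params=10, q=4)
        assert rep.agfi is None and rep.rmsea is None

    def test_aic_nested_difference_exact(self, chain_model):
        theta = np.array([0.6, 0.5, 1, 1, 1])
        S, _ = sample_cov(chain_model, theta, 2000, 5)
        fm_small = tg.fit_model(chain_model, S, 2000)
        bigger = chain_model.copy()
        bigger.add_edge("x1", "x3")
        fm_big = tg.fit_model(bigger, S, 2000)
        d_aic = fm_big.fit_report.aic - fm_small.fit_report.aic
        d_chi = fm_big.chi2 - fm_small.chi2
        assert d_aic == pytest.approx(d_chi + 2, abs=1e-8)


class TestModificationIndices:
    def test_free_candidate_rejected(self, two_node_model):
        S, _ = sample_cov(two_node_model, np.array([0.5, 1, 1]), 500, 1)
        fm = tg.fit_model(two_node_model, S, 500)
        with pytest.raises(ValueError, match="already free"):
            tg.modification_indices(fm, [("edge", ("x1", "x2"))])

    def test_approximates_refit_chi2_drop(self):
        """MI within 15% of the actual chi-square drop from freeing the
        omitted modest direct effect (n = 5000, 10 seeds)."""
        for seed in range(10):
            truth = tg.PathModel(nodes=["x1", "x2", "x3"])
            truth.add_edge("x1", "x2")
            truth.add_edge("x2", "x3")
            truth.add_edge("x1", "x3")
            S, _ = sample_cov(truth, np.array([0.6, 0.6, 0.2, 1, 1, 1]),
                              5000, seed)
            fitted = tg.PathModel(nodes=["x1", "x2", "x3"])
            fitted.add_edge("x1", "x2")
            fitted.add_edge("x2", "x3")
            fm = tg.fit_model(fitted, S, 5000, compute_se=False)
            mi = dict(tg.modification_indices(
                fm, [("edge", ("x1", "x3"))]))[("edge", ("x1", "x3"))]
            refit = fitted.copy()
            refit.add_edge("x1", "x3")
            fm2 = tg.fit_model(refit, S, 5000, compute_se=False)
            dchi = fm.chi2 - fm2.chi2
            assert abs(mi - dchi) / dchi < 0.15

    @pytest.mark.parametrize("seed", range(50))
    def test_nonnegative_on_random_models(self, seed):
        rng = np.random.default_rng(seed)
        model, theta = random_path_model(rng, 4)
        S, _ = sample_cov(model, theta, 300, seed)
        fm = tg.fit_model(model, S, 300, compute_se=False,
                          check_identification=False)
        cands = [("edge", (s, t)) for s in model.nodes for t in model.nodes
                 if s != t and (s, t) not in model.edges][:5]
        for _, mi in tg.modification_indices(fm, cands):
            assert mi >= 0


class TestIndependenceBaseline:
    def test_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 4))
        x[:, 1] += x[:, 0]
        S = np.cov(x, rowvar=False, ddof=1)
        chi2, df = independence_chi2(S, 200)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        assert chi2 == pytest.approx(-199 * np.log(np.linalg.det(R)),
                                     rel=1e-10)
        assert df == 6


class TestEstimatorWrapper:
    def test_fit_from_samples(self, two_node_model):
        _, df = sample_cov(two_node_model, np.array([0.5, 1, 1]), 4000, 2)
        est = tg.StructuralEquationModel(two_node_model).fit(df)
        assert abs(est.params_["x1->x2"] - 0.5) < 0.1
        assert est.df_ == 0
        assert est.fit_report_.chi2 == pytest.approx(est.chi2_)

    def test_params_protocol(self, two_node_model):
        est = tg.StructuralEquationModel(two_node_model)
        assert est.get_params()["bias"] == "n-1"
        with pytest.raises(ValueError):
            est.set_params(nope=1)
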