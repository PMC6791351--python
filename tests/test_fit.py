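import math

import numpy as np
import pytest
from scipy import stats

import misstaxa as mt
from misstaxa.fit import FitResult, MODEL_K
from conftest import cherry_painting


class TestCovariances:
    def test_bm_hand_example(self, three_tip_tree):
        np.testing.assert_allclose(mt.bm_covariance(three_tip_tree),
                                   [[1.0, 0.5, 0.0],
                                    [0.5, 1.0, 0.0],
                                    [0.0, 0.0, 1.0]])

    def test_bm_positive_semidefinite_on_yule(self, yule50):
        eig = np.linalg.eigvalsh(mt.bm_covariance(yule50))
        assert eig.min() > -1e-10

    def test_bms_single_regime_collapses_to_bm(self, yule50):
        paint = mt.RegimePainting(np.zeros(yule50.n_nodes, dtype=np.int8))
        V = mt.bms_covariance(yule50, paint, (0.7, 99.0))
        np.testing.assert_allclose(V, 0.7 * mt.bm_covariance(yule50), atol=1e-12)

    def test_bms_equal_rates_ignore_painting(self, yule50):
        paint = mt.simulate_mk_regimes(yule50, 0.5, seed=1)
        V = mt.bms_covariance(yule50, paint, (0.5, 0.5))
        np.testing.assert_allclose(V, 0.5 * mt.bm_covariance(yule50), atol=1e-12)

    def test_bms_per_edge_accumulation(self, cherry_pair_tree):
        # A,B tip edges in regime 1 (rate 1), everything else regime 0 (rate .5)
        paint = cherry_painting(cherry_pair_tree)
        V = mt.bms_covariance(cherry_pair_tree, paint, (0.5, 1.0))
        lab = cherry_pair_tree.tip_labels  # A,B,C,D
        i = {t: k for k, t in enumerate(lab)}
        assert V[i["A"], i["A"]] == pytest.approx(0.5 + 1.0)
        assert V[i["A"], i["B"]] == pytest.approx(0.5)
        assert V[i["C"], i["C"]] == pytest.approx(1.0)
        assert V[i["C"], i["D"]] == pytest.approx(0.5)
        assert V[i["A"], i["C"]] == pytest.approx(0.0)

    def test_ou_two_tip_diagonal(self, two_tip_tree):
        V = mt.ou_covariance(two_tip_tree, 1.5)
        want = (1.0 / 3.0) * (1.0 - math.exp(-3.0))
        np.testing.assert_allclose(V, [[want, 0.0], [0.0, want]])

    def test_ou_small_alpha_limit_is_bm(self, yule50):
        V = mt.ou_covariance(yule50, 1e-8)
        C = mt.bm_covariance(yule50)
        mask = C > 0
        assert np.max(np.abs(V[mask] - C[mask]) / C[mask]) < 1e-5

    def test_ou_diagonal_constant_on_unit_tree(self, yule50):
        V = mt.ou_covariance(yule50, 1.5)
        want = (1.0 / 3.0) * (1.0 - math.exp(-3.0))
        np.testing.assert_allclose(np.diag(V), want, atol=1e-8)


class TestWeightMatrix:
    def test_single_regime_gives_single_active_column(self, yule50):
        paint = mt.RegimePainting(np.zeros(yule50.n_nodes, dtype=np.int8))
        W = mt.ou_weight_matrix(yule50, paint, 1.5)
        np.testing.assert_allclose(W[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(W[:, 1], 0.0, atol=1e-12)

    def test_regime_shift_segment_integral(self, cherry_pair_tree):
        # root regime 0; the A,B cherry's parent switches to regime 1, so the
        # terminal unit-length edge of tip A evolves toward theta_1
        paint = cherry_painting(cherry_pair_tree)
        W = mt.ou_weight_matrix(cherry_pair_tree, paint, 1.5)
        a = cherry_pair_tree.tip_id("A")
        c = cherry_pair_tree.tip_id("C")
        assert W[a, 1] == pytest.approx(1.0 - math.exp(-1.5))
        assert W[a, 0] == pytest.approx(math.exp(-1.5))
        assert W[c, 1] == pytest.approx(0.0)

    def test_rows_sum_to_one_for_any_painting_and_alpha(self, yule50):
        rng = np.random.default_rng(2)
        for alpha in (1e-4, 0.3, 1.5, 20.0):
            paint = mt.simulate_mk_regimes(yule50, 0.5, seed=rng)
            W = mt.ou_weight_matrix(yule50, paint, alpha)
            np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)


class TestGlsProfile:
    def test_iid_case_reduces_to_sample_moments(self):
        x = np.array([1.0, 2.0, 3.0, 6.0])
        beta, s2, _ = mt.gls_profile(x, np.eye(4), np.ones((4, 1)))
        assert beta[0] == pytest.approx(x.mean())
        assert s2 == pytest.approx(np.mean((x - x.mean()) ** 2))

    def test_two_point_closed_form_loglik(self):
        _, s2, logL = mt.gls_profile(np.array([0.0, 2.0]), np.eye(2),
                                     np.ones((2, 1)))
        assert s2 == pytest.approx(1.0)
        assert logL == pytest.approx(-(math.log(2 * math.pi) + 1.0), abs=1e-10)

    def test_scale_profiling_identity(self, yule50):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        V = mt.bm_covariance(yule50) + 1e-6 * np.eye(50)
        _, s2a, la = mt.gls_profile(x, V, np.ones((50, 1)))
        _, s2b, lb = mt.gls_profile(x, 7.0 * V, np.ones((50, 1)))
        assert la == pytest.approx(lb, abs=1e-8)
        assert s2a == pytest.approx(7.0 * s2b, rel=1e-8)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("model", ["BM", "BMS", "OU", "OUM"])
    def test_loglik_matches_explicit_multivariate_normal(self, model):
        """Fit-side likelihood at the true parameters equals the explicit
        Gaussian density built from the analytic mean and covariance."""
        for seed in (101, 102):
            tree = mt.simulate_yule_tree(15, seed=seed)
            paint = mt.simulate_mk_regimes(tree, 0.5, seed=seed + 1)
            spec = mt.ModelSpec.study_default(model)
            trait = mt.simulate_trait(tree, paint, spec, seed=seed + 2)
            x = trait.reindex(tree.tip_labels).to_numpy()
            d = tree.tip_depths()
            if model == "BM":
                V = 0.5 * tree.mrca_depths()
                m = np.full(15, 10.0)
            elif model == "BMS":
                V = mt.bms_covariance(tree, paint, (0.5, 1.0))
                m = np.full(15, 10.0)
            elif model == "OU":
                V = 0.5 * mt.ou_covariance(tree, 1.5)
                m = np.full(15, 10.0)  # root starts at the optimum
            else:
                V = 0.5 * mt.ou_covariance(tree, 1.5)
                m = mt.ou_weight_matrix(tree, paint, 1.5) @ np.array([10.0, 11.0])
            want = stats.multivariate_normal(mean=m, cov=V).logpdf(x)
            got = mt.model_loglik(tree, paint, trait, spec)
            assert got == pytest.approx(want, abs=1e-8)


class TestFitModel:
    @pytest.fixture(scope="class")
    def oum_data(self):
        tree = mt.simulate_yule_tree(120, seed=51)
        paint = mt.simulate_mk_regimes(tree, 0.5, seed=52)
        trait = mt.simulate_trait(tree, paint, mt.ModelSpec.study_default("OUM"),
                                  seed=53)
        return tree, paint, trait

    def test_parameter_counts(self, oum_data):
        tree, paint, trait = oum_data
        fits = mt.fit_all(tree, paint, trait)
        for m, f in fits.items():
            assert f.k == MODEL_K[m]
            assert f.n == 120
            assert f.params["sigma2_0"] > 0
            assert f.aicc == pytest.approx(mt.aicc(f.loglik, f.k, f.n))

    def test_nested_models_dominate_in_loglik(self, oum_data):
        tree, paint, trait = oum_data
        fits = mt.fit_all(tree, paint, trait)
        tol = 1e-6
        assert fits["BMS"].loglik >= fits["BM"].loglik - tol
        assert fits["OUM"].loglik >= fits["OU"].loglik - tol
        assert fits["OU"].loglik >= fits["BM"].loglik - tol  # BM is the a->0 limit

    def test_bm_rate_recovery(self):
        rng = np.random.default_rng(61)
        est = []
        for _ in range(25):
            tree = mt.simulate_yule_tree(100, seed=rng)
            trait = mt.simulate_trait(tree, None, mt.ModelSpec.study_default("BM"),
                                      seed=rng)
            est.append(mt.fit_model(tree, None, trait, "BM").params["sigma2_0"])
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_constant_trait_flagged_degenerate(self, yule50):
        import pandas as pd

        trait = pd.Series(np.full(50, 3.0), index=yule50.tip_labels)
        f = mt.fit_model(yule50, None, trait, "BM")
        assert not f.converged

    def test_fit_requires_minimum_tips(self, three_tip_tree):
        import pandas as pd

        trait = pd.Series([1.0, 2.0, 3.0], index=three_tip_tree.tip_labels)
        with pytest.raises(ValueError):
            mt.fit_model(three_tip_tree, None, trait, "BM")

    def test_multi_regime_fit_requires_both_regimes(self, yule50):
        import pandas as pd

        paint = mt.RegimePainting(np.zeros(yule50.n_nodes, dtype=np.int8))
        trait = pd.Series(np.random.default_rng(0).normal(size=50),
                          index=yule50.tip_labels)
        with pytest.raises(ValueError):
            mt.fit_model(yule50, paint, trait, "OUM")


class TestModelChoice:
    def _fr(self, model, aicc_value):
        return FitResult(model=model, params={}, loglik=0.0, k=MODEL_K[model],
                         n=300, aicc=aicc_value)

    def test_aicc_spot_values(self):
        assert mt.aicc(0.0, 2, 300) == pytest.approx(4.0 + 12.0 / 297)
        assert mt.aicc(0.0, 4, 300) == pytest.approx(8.0 + 40.0 / 295)
        # correction vanishes for large n
        assert mt.aicc(0.0, 3, 10**9) == pytest.approx(6.0, abs=1e-6)

    def test_aicc_requires_enough_observations(self):
        with pytest.raises(ValueError):
            mt.aicc(0.0, 4, 5)

    def test_select_best_deltas(self):
        results = [self._fr("BM", 10.0), self._fr("BMS", 12.0),
                   self._fr("OU", 11.0), self._fr("OUM", 13.0)]
        best, deltas = mt.select_best(results)
        assert best == "BM"
        assert deltas == {"BM": 0.0, "BMS": 2.0, "OU": 1.0, "OUM": 3.0}

    def test_exact_tie_goes_to_fewer_parameters(self):
        best, _ = mt.select_best([self._fr("OU", 10.0), self._fr("BM", 10.0)])
        assert best == "BM"

    def test_lrt_decisions(self):
        bm = FitResult("BM", {}, loglik=-10.0, k=2, n=300, aicc=0.0)
        ou_same = FitResult("OU", {}, loglik=-10.0, k=3, n=300, aicc=0.0)
        ou_better = FitResult("OU", {}, loglik=-7.5, k=3, n=300, aicc=0.0)
        assert mt.lrt_bm_vs_ou(bm, ou_same) == "BM"
        assert mt.lrt_bm_vs_ou(bm, ou_better) == "OU"  # 2*2.5 = 5 > 3.841

    def test_lrt_mismatched_sample_sizes_error(self):
        bm = FitResult("BM", {}, loglik=-10.0, k=2, n=300, aicc=0.0)
        ou = FitResult("OU", {}, loglik=-9.0, k=3, n=200, aicc=0.0)
        with pytest.raises(ValueError):
            mt.lrt_bm_vs_ou(bm, ou)
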