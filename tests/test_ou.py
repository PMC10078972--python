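import numpy as np
import pytest
import scipy.stats

from climniche import (
    FitConfig,
    OUParams,
    Phylo,
    RegimePainting,
    aicc,
    aicc_weights,
    central_hessian,
    compare_models,
    fit_model,
    half_life,
    ou_loglik,
    ou_moments,
    paint_regimes,
    simulate_discrete,
    simulate_ou,
    simulate_tree,
    stationary_variance,
)
from _oracles import dense_mvn_loglik, mc_tip_moments


def single_regime(tree):
    return RegimePainting(regime=np.zeros(tree.n_nodes, dtype=int), labels=["g"])


def two_regime_painting(tree, rng):
    """Random but valid painting: regimes constant within clades."""
    Q = np.array([[-0.4, 0.4], [0.4, -0.4]])
    sim = simulate_discrete(tree, Q, np.array([0.6, 0.4]),
                            seed=int(rng.integers(2**31 - 1)))
    tips = {tree.tips[i]: ["g", "a"][sim.node_states[i]]
            for i in range(tree.n_tips)}
    nodes = {v: ["g", "a"][sim.node_states[v]] for v in range(tree.n_nodes)}
    return paint_regimes(tree, tips, nodes, labels=["g", "a"])


class TestPainting:
    def test_all_ground(self, five_tip):
        tips = {t: "g" for t in five_tip.tips}
        nodes = {v: "g" for v in range(five_tip.n_nodes)}
        p = paint_regimes(five_tip, tips, nodes, labels=["g", "a"])
        assert np.all(p.regime == 0)

    def test_one_arboreal_clade_rootward_rule(self, five_tip):
        # clade (a,b): its stem takes the state of the clade's parent (g),
        # branches inside the clade take their parent's state (a)
        idx = {t: i for i, t in enumerate(five_tip.tips)}
        mrca_ab = five_tip.parent[idx["a"]]
        nodes = {v: "g" for v in range(five_tip.n_nodes)}
        nodes[mrca_ab] = "a"
        tips = {t: ("a" if t in ("a", "b") else "g") for t in five_tip.tips}
        p = paint_regimes(five_tip, tips, nodes, labels=["g", "a"])
        expected = np.zeros(five_tip.n_nodes, dtype=int)
        expected[idx["a"]] = expected[idx["b"]] = 1  # children of the a-node
        np.testing.assert_array_equal(p.regime, expected)

    def test_tipward_option_switches_terminal(self, five_tip):
        idx = {t: i for i, t in enumerate(five_tip.tips)}
        nodes = {v: "g" for v in range(five_tip.n_nodes)}
        tips = {t: "g" for t in five_tip.tips}
        tips["c"] = "a"
        p = paint_regimes(five_tip, tips, nodes, labels=["g", "a"],
                          terminal="tipward")
        assert p.regime[idx["c"]] == 1
        assert p.regime[idx["a"]] == 0

    def test_missing_node_state(self, five_tip):
        with pytest.raises(ValueError, match="missing state"):
            paint_regimes(five_tip, {t: "g" for t in five_tip.tips}, {},
                          labels=["g"])


class TestMoments:
    def test_constant_mean_at_optimum(self, quartet):
        p = single_regime(quartet)
        params = OUParams(model="OU1", theta0=4.0, theta=[4.0], alpha=[1.3],
                          sigma2=[0.7])
        mean, _ = ou_moments(quartet, p, params)
        np.testing.assert_allclose(mean, 4.0)

    def test_bm_limit_covariance_is_shared_path(self, quartet):
        p = single_regime(quartet)
        s2 = 0.9
        params = OUParams(model="BM1", theta0=0.0, theta=[0.0], alpha=[0.0],
                          sigma2=[s2])
        _, cov = ou_moments(quartet, p, params)
        depths = quartet.node_depths()
        M = quartet.mrca_matrix()
        np.testing.assert_allclose(cov, s2 * depths[M], atol=1e-12)

    @pytest.mark.parametrize("model,alpha,sigma2", [
        ("OUMVA", [0.8, 2.0], [1.0, 0.3]),
        ("OUM", [0.8, 0.8], [0.5, 0.5]),
        ("BMS", [0.0, 0.0], [1.0, 0.25]),
    ])
    def test_monte_carlo_oracle(self, model, alpha, sigma2):
        rng = np.random.default_rng(17)
        tree = simulate_tree(6, 1.0, 0.0, seed=23)
        painting = two_regime_painting(tree, rng)
        params = OUParams(model=model, theta0=0.0, theta=[0.0, 3.0],
                          alpha=alpha, sigma2=sigma2)
        mean, cov = ou_moments(tree, painting, params)
        sim = simulate_ou(tree, painting, params, seed=99, n_reps=50_000)
        m, m_se, c, c_se = mc_tip_moments(sim.tip_values)
        assert np.all(np.abs(mean - m) <= 3 * m_se)
        assert np.all(np.abs(cov - c) <= 3 * c_se)


class TestLoglik:
    def test_single_tip_univariate(self):
        lnl = ou_loglik(np.array([1.2]), np.array([0.5]), np.array([[2.0]]))
        assert lnl == pytest.approx(
            scipy.stats.norm.logpdf(1.2, 0.5, np.sqrt(2.0)), abs=1e-9
        )

    def test_two_independent_tips(self):
        y = np.array([0.3, -1.1])
        mean = np.array([0.0, 0.0])
        cov = np.diag([1.5, 0.7])
        expected = (scipy.stats.norm.logpdf(0.3, 0, np.sqrt(1.5))
                    + scipy.stats.norm.logpdf(-1.1, 0, np.sqrt(0.7)))
        assert ou_loglik(y, mean, cov) == pytest.approx(expected, abs=1e-9)

    def test_dense_formula_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((5, 7))
        cov = A @ A.T / 7 + np.eye(5)
        y = rng.standard_normal(5)
        mean = rng.standard_normal(5)
        assert ou_loglik(y, mean, cov) == pytest.approx(
            dense_mvn_loglik(y, mean, cov), abs=1e-7
        )


class TestNestingIdentities:
    """Sub-models evaluated at matched parameters give identical likelihoods."""

    def setup_method(self):
        rng = np.random.default_rng(31)
        self.tree = simulate_tree(40, 1.0, 0.0, seed=41)
        self.painting = two_regime_painting(self.tree, rng)
        self.y = rng.standard_normal(40) + 2.0

    def _lnl(self, model, theta0, theta, alpha, sigma2):
        params = OUParams(model=model, theta0=theta0, theta=theta,
                          alpha=alpha, sigma2=sigma2)
        mean, cov = ou_moments(self.tree, self.painting, params)
        return ou_loglik(self.y, mean, cov)

    def test_oum_with_equal_optima_is_ou1(self):
        a = self._lnl("OUM", 1.0, [2.5, 2.5], [0.6, 0.6], [0.8, 0.8])
        b = self._lnl("OU1", 1.0, [2.5, 2.5], [0.6, 0.6], [0.8, 0.8])
        assert a == pytest.approx(b, abs=1e-6)

    def test_oumva_all_shared_is_ou1(self):
        a = self._lnl("OUMVA", 1.0, [2.5, 2.5], [0.6, 0.6], [0.8, 0.8])
        b = self._lnl("OU1", 1.0, [2.5, 2.5], [0.6, 0.6], [0.8, 0.8])
        assert a == pytest.approx(b, abs=1e-6)

    def test_bms_shared_rate_is_bm1(self):
        a = self._lnl("BMS", 1.0, [0.0, 0.0], [0.0, 0.0], [0.9, 0.9])
        b = self._lnl("BM1", 1.0, [0.0, 0.0], [0.0, 0.0], [0.9, 0.9])
        assert a == pytest.approx(b, abs=1e-6)

    def test_vanishing_alpha_reaches_bm(self):
        a = self._lnl("OU1", 1.0, [1.0, 1.0], [1e-9, 1e-9], [0.9, 0.9])
        b = self._lnl("BM1", 1.0, [1.0, 1.0], [0.0, 0.0], [0.9, 0.9])
        assert a == pytest.approx(b, abs=1e-6)


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_aicc_undefined_small_n(self):
        with pytest.raises(ValueError):
            aicc(0.0, 4, 5)

    def test_equal_values_equal_weights(self):
        np.testing.assert_allclose(aicc_weights([10.0, 10.0]), [0.5, 0.5])

    def test_delta_two_weights(self):
        w = aicc_weights([0.0, 2.0])
        np.testing.assert_allclose(w, [0.73105858, 0.26894142], atol=5e-7)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = aicc_weights(rng.uniform(100, 200, size=7))
            assert w.sum() == pytest.approx(1.0)


class TestDerived:
    def test_half_life(self):
        assert half_life(np.array([np.log(2)]))[0] == pytest.approx(1.0)
        assert half_life(np.array([0.0]))[0] == np.inf

    def test_stationary_variance(self):
        assert stationary_variance(np.array([1.0]), np.array([2.0]))[0] == \
            pytest.approx(1.0)
        assert stationary_variance(np.array([0.0]), np.array([2.0]))[0] == np.inf


class TestHessianMachinery:
    def test_quadratic_oracle(self):
        H_true = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])

        def f(x):
            return 0.5 * x @ H_true @ x + x.sum()

        x0 = np.array([0.3, -0.2, 1.4])
        H = central_hessian(f, x0, np.full(3, 1e-3))
        np.testing.assert_allclose(H, H_true, atol=1e-4)

    def test_boundary_stuck_alpha_flagged(self):
        # Brownian data fitted with OU1: alpha runs to its floor and the fit
        # must not pass the curvature diagnostic
        rng = np.random.default_rng(8)
        tree = simulate_tree(60, 1.0, 0.0, seed=14)
        p = single_regime(tree)
        bm = OUParams(model="BM1", theta0=0.0, theta=[0.0], alpha=[0.0],
                      sigma2=[1.0])
        y = simulate_ou(tree, p, bm, seed=15).tip_values[0]
        fit = fit_model(tree, p, y, "OU1", FitConfig(n_restarts=2, seed=0))
        if fit.at_bound:
            assert fit.diagnostic_pass is False


class TestRootStateAliasing:
    def test_shared_alpha_ultrametric_aliases_theta0(self):
        # on an ultrametric tree the theta0 weight column is exactly
        # collinear with the theta columns for shared-alpha models
        rng = np.random.default_rng(80)
        tree = simulate_tree(80, 1.0, 0.0, seed=81)
        painting = two_regime_painting(tree, rng)
        true = OUParams(model="OUM", theta0=5.0, theta=[5.0, 9.0],
                        alpha=[0.4, 0.4], sigma2=[0.5, 0.5])
        y = simulate_ou(tree, painting, true, seed=82).tip_values[0]
        fit = fit_model(tree, painting, y, "OUM", FitConfig(n_restarts=1, seed=0))
        assert fit.theta0_aliased
        root_reg = painting.regime[tree.root]
        assert fit.params.theta0 == fit.params.theta[root_reg]

    def test_strong_pull_near_alias_keeps_diagnostic_sound(self):
        # with per-regime pulls so strong that e^(-alpha T) ~ 0, theta0 is
        # effectively unidentifiable; the fold keeps the curvature check
        # meaningful instead of rejecting on numerically-zero eigenvalues
        rng = np.random.default_rng(85)
        tree = simulate_tree(200, 1.0, 0.5, seed=86)
        painting = two_regime_painting(rng=rng, tree=tree)
        true = OUParams(model="OUMVA", theta0=20.0, theta=[20.0, 25.0],
                        alpha=[1.2, 1.6], sigma2=[1.0, 0.4])
        y = simulate_ou(tree, painting, true, seed=87).tip_values[0]
        fit = fit_model(tree, painting, y, "OUMVA", FitConfig(n_restarts=2, seed=0))
        assert fit.theta0_aliased
        assert fit.diagnostic_pass is True


class TestFitting:
    def test_oum_recovery_and_ranking(self):
        rng = np.random.default_rng(55)
        tree = simulate_tree(150, 1.0, 0.0, seed=56)
        painting = two_regime_painting(tree, rng)
        true = OUParams(model="OUM", theta0=10.0, theta=[10.0, 16.0],
                        alpha=[0.7, 0.7], sigma2=[1.0, 1.0])
        y = simulate_ou(tree, painting, true, seed=57).tip_values[0]
        cfg = FitConfig(n_restarts=2, seed=0)
        fit = fit_model(tree, painting, y, "OUM", cfg)
        assert abs(fit.params.theta[0] - 10.0) / 10.0 < 0.1
        assert abs(fit.params.theta[1] - 16.0) / 16.0 < 0.1
        bm = fit_model(tree, painting, y, "BM1", cfg)
        assert fit.aicc < bm.aicc

    def test_nested_likelihood_ordering(self):
        rng = np.random.default_rng(60)
        tree = simulate_tree(80, 1.0, 0.0, seed=61)
        painting = two_regime_painting(tree, rng)
        true = OUParams(model="OUMV", theta0=0.0, theta=[0.0, 4.0],
                        alpha=[0.6, 0.6], sigma2=[1.0, 0.4])
        y = simulate_ou(tree, painting, true, seed=62).tip_values[0]
        cfg = FitConfig(n_restarts=2, seed=0, diagnostics=False)
        lnls = {m: fit_model(tree, painting, y, m, cfg).lnL
                for m in ("OU1", "OUM", "OUMV", "OUMVA", "BM1", "BMS")}
        tol = 1e-4
        assert lnls["OUMVA"] >= lnls["OUMV"] - tol
        assert lnls["OUMV"] >= lnls["OUM"] - tol
        assert lnls["OUM"] >= lnls["OU1"] - tol
        assert lnls["BMS"] >= lnls["BM1"] - tol

    def test_regime_relabel_permutes_estimates(self):
        rng = np.random.default_rng(70)
        tree = simulate_tree(60, 1.0, 0.0, seed=71)
        painting = two_regime_painting(tree, rng)
        flipped = RegimePainting(regime=1 - painting.regime,
                                 labels=painting.labels[::-1])
        true = OUParams(model="OUMV", theta0=0.0, theta=[0.0, 4.0],
                        alpha=[0.6, 0.6], sigma2=[1.0, 0.4])
        y = simulate_ou(tree, painting, true, seed=72).tip_values[0]
        cfg = FitConfig(n_restarts=2, seed=0, diagnostics=False)
        a = fit_model(tree, painting, y, "OUMV", cfg)
        b = fit_model(tree, flipped, y, "OUMV", cfg)
        assert a.lnL == pytest.approx(b.lnL, abs=1e-4)
        np.testing.assert_allclose(a.params.theta, b.params.theta[::-1],
                                   rtol=1e-2)

    def test_trait_mapping_and_missing_tip(self, quartet):
        p = single_regime(quartet)
        with pytest.raises(ValueError, match="missing"):
            fit_model(quartet, p, {"a": 1.0}, "BM1")
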