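import itertools
import math

import numpy as np
import pytest
from scipy import stats

import gsgprobit as g
from gsgprobit.model import SigmaOperator
from gsgprobit.sampler import _Engine, _mh_c_step

import helpers


def _identity_dataset(n):
    X = np.ones((n, 1))
    Y = np.tile([1, 0], n // 2)
    return g.ExpressionDataset(X=X, Y=Y)


class TestUpdateZ:
    def test_signs_always_match_labels(self, tiny, tiny_cfg, rng):
        gv = g.GammaVector(np.array([1, 1, 0]))
        op = g.build_sigma(gv, 2.0, tiny.X, tiny_cfg.h)
        st = g.ChainState(Z=np.where(tiny.Y == 1, 0.5, -0.5).astype(float),
                          gamma=gv, c=2.0)
        for _ in range(200):
            st.Z = g.update_Z(st, op, tiny.Y, rng)
            assert np.all((st.Z > 0) == (tiny.Y == 1))

    def test_half_normal_mean_identity_sigma(self):
        """With Sigma = I the positive-class conditionals are standard
        half-normals: mean sqrt(2/pi)."""
        n = 1000
        ds = _identity_dataset(n)
        op = SigmaOperator(np.zeros((n, 0)), c=1.0, h=0.0, n=n)
        st = g.ChainState(Z=np.where(ds.Y == 1, 0.5, -0.5).astype(float),
                          gamma=g.GammaVector(np.zeros(1, dtype=int)), c=1.0)
        rng = np.random.default_rng(77)
        pos = []
        for _ in range(100):  # 100 sweeps x 500 positive sites = 5e4 draws
            st.Z = g.update_Z(st, op, ds.Y, rng)
            pos.append(st.Z[ds.Y == 1])
        pos = np.concatenate(pos)
        assert pos.mean() == pytest.approx(math.sqrt(2 / math.pi), abs=0.01)
        neg = st.Z[ds.Y == 0]
        assert np.all(neg <= 0) and np.all(pos > 0)

    def test_conditional_moments_n2_known_sigma(self):
        """Empirical truncated-normal conditional moments on n=2 vs the
        closed-form formulas."""
        X = np.array([[1.0], [1.0]])
        ds = g.ExpressionDataset(X=X, Y=np.array([1, 0]))
        op = g.build_sigma(g.GammaVector(np.array([1])), 1.0, X, 0.0)
        S = op.dense()  # [[1.5, .5], [.5, 1.5]]
        rho = S[0, 1] / S[0, 0]
        st = g.ChainState(Z=np.array([0.5, -0.5]),
                          gamma=g.GammaVector(np.array([1])), c=1.0)
        rng = np.random.default_rng(5)
        zs = []
        for _ in range(40000):
            st.Z = g.update_Z(st, op, ds.Y, rng)
            zs.append(st.Z.copy())
        zs = np.array(zs[2000:])
        # oracle: conditional of Z_0 | Z_1 is N(rho z1, s2) truncated > 0
        s2 = S[0, 0] - S[0, 1] ** 2 / S[1, 1]
        z1 = zs[:, 1]
        alpha = (0 - rho * z1) / math.sqrt(s2)
        lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        expected_mean = float(np.mean(rho * z1 + math.sqrt(s2) * lam))
        got = float(np.mean(zs[:, 0]))
        se = zs[:, 0].std() / math.sqrt(len(zs) / 20)  # conservative ESS
        assert abs(got - expected_mean) < 2 * se + 0.02


class TestGammaFlipProb:
    def test_prior_recovered_when_rho_is_one(self, tiny, tiny_cfg):
        """Flipping a duplicated gene leaves Sigma unchanged (rho = 1), so
        the conditional probability equals the prior pi."""
        z = np.array([0.4, -0.3, 0.6, -0.2])
        # gene 2 duplicates gene 0, which is already selected
        st = g.ChainState(Z=z, gamma=g.GammaVector(np.array([1, 0, 1])), c=2.0)
        p = g.gamma_flip_prob(2, st, tiny, tiny_cfg)
        assert p == pytest.approx(0.2, rel=1e-9)  # pi = 0.2

    def test_reduces_to_prior_odds_formula(self, tiny):
        cfg = g.ModelConfig(h=1.0, pi=0.005)
        z = np.array([0.4, -0.3, 0.6, -0.2])
        st = g.ChainState(Z=z, gamma=g.GammaVector(np.array([1, 0, 1])), c=2.0)
        # rho = 1 case (duplicated gene): (1 + (1-pi)/pi)^-1 = pi
        assert g.gamma_flip_prob(2, st, tiny, cfg) == pytest.approx(0.005, rel=1e-9)

    def test_matches_dense_enumeration_ratio(self, rng):
        """p(gamma_i=1 | ...) equals the two-configuration density ratio
        computed entirely through dense linear algebra."""
        n, p = 4, 3
        X = rng.standard_normal((n, p))
        ds = g.ExpressionDataset(X=X, Y=np.array([1, 0, 1, 0]))
        cfg = g.ModelConfig(h=1.5, pi=0.3)
        z = rng.standard_normal(n)
        pi = cfg.pi_vector(p)
        for base in [[0, 0, 0], [1, 0, 1], [0, 1, 0]]:
            st = g.ChainState(Z=z, gamma=g.GammaVector(np.array(base)), c=1.7)
            for i in range(p):
                ours = g.gamma_flip_prob(i, st, ds, cfg)
                sel1 = sorted(set(np.flatnonzero(st.gamma.flipped(i, 1).gamma)))
                sel0 = sorted(set(np.flatnonzero(st.gamma.flipped(i, 0).gamma)))
                l1 = helpers.dense_log_marginal(z, X, sel1, 1.7, cfg.h, pi)
                l0 = helpers.dense_log_marginal(z, X, sel0, 1.7, cfg.h, pi)
                ref = 1.0 / (1.0 + math.exp(l0 - l1))
                assert ours == pytest.approx(ref, rel=1e-9)


class TestUpdateGamma:
    def test_prior_domination_limits(self, tiny, rng):
        z = np.zeros(4)  # uninformative latent vector -> rho near 1
        st = g.ChainState(Z=z, gamma=g.GammaVector(np.zeros(3, dtype=int)), c=1.0)
        never = g.ModelConfig(h=1.0, pi=1e-12)
        for _ in range(50):
            assert g.update_gamma(st, tiny, never, rng).p_gamma == 0
        always = g.ModelConfig(h=1.0, pi=1 - 1e-12)
        st2 = g.ChainState(Z=z, gamma=g.GammaVector(np.ones(3, dtype=int)), c=1.0)
        for _ in range(50):
            assert g.update_gamma(st2, tiny, always, rng).p_gamma == 3

    def test_sweep_stationary_distribution_small(self, rng):
        """Short sanity version of the enumeration check (the full-length
        run lives in the acceptance suite)."""
        X = np.random.default_rng(11).standard_normal((5, 3))
        ds = g.ExpressionDataset(X=X, Y=np.array([1, 0, 1, 1, 0]))
        cfg = g.ModelConfig(h=1.0, pi=0.25)
        z = np.where(ds.Y == 1, 0.8, -0.7).astype(float)
        exact = helpers.enumerate_gamma_distribution(z, ds, 2.0, cfg)
        st = g.ChainState(Z=z, gamma=g.GammaVector(np.zeros(3, dtype=int)), c=2.0)
        counts = {k: 0 for k in exact}
        sweeps = 8000
        for _ in range(sweeps):
            st.gamma = g.update_gamma(st, ds, cfg, rng)
            counts[tuple(st.gamma.gamma.tolist())] += 1
        tv = 0.5 * sum(abs(counts[k] / sweeps - exact[k]) for k in exact)
        assert tv < 0.05

    def test_incremental_engine_matches_flip_prob_api(self, small_synth, rng):
        """The engine's scalar fast path and the two-SigmaOperator API
        route agree on every flip probability along a trajectory."""
        train, _, _ = small_synth
        cfg = g.ModelConfig(h=100.0, pi=0.1)
        eng = _Engine(train.X, train.Y, cfg)
        z = np.where(train.Y == 1, 0.6, -0.6).astype(float)
        eng.set_state(z, [0, 5], 4.0)
        st = g.ChainState(Z=z, gamma=g.GammaVector.from_selected([0, 5], train.p), c=4.0)
        ld_cur, q_cur = eng.logdet_quad()
        for j in range(train.p):
            if j in eng.sel:
                m0, a, b_, c_, _ = eng._removed_scalars(j)
                ld0, qd0 = helpers_ldq(eng, m0, a, b_, c_)
                ld1, qd1 = ld_cur, q_cur
            else:
                m1, a, b_, c_, _ = eng._added_scalars(j)
                ld1, qd1 = helpers_ldq(eng, m1, a, b_, c_)
                ld0, qd0 = ld_cur, q_cur
            log_rho = 0.5 * (ld1 - ld0) + 0.5 * (qd1 - qd0)
            pi_j = cfg.pi_vector(train.p)[j]
            fast = 1.0 / (1.0 + (1 - pi_j) / pi_j * math.exp(log_rho))
            api = g.gamma_flip_prob(j, st, train, cfg)
            assert fast == pytest.approx(api, rel=1e-8)


def helpers_ldq(eng, m, q11, qzz, qz1):
    from gsgprobit.sampler import _logdet_quad

    return _logdet_quad(m, q11, qzz, qz1, eng.sumz, eng.zz, eng.h, eng.c, eng.n)


class TestUpdateC:
    def test_mode_property_of_optimizer(self, tiny, tiny_cfg):
        eng = _Engine(tiny.X, tiny.Y, tiny_cfg)
        eng.set_state(np.array([0.5, -0.4, 0.7, -0.3]), [0, 1], 2.0)
        from gsgprobit.sampler import _default_proposal

        c_opt, _ = _default_proposal(eng)
        assert eng.log_cond_c(c_opt) >= eng.log_cond_c(0.5 * c_opt)
        assert eng.log_cond_c(c_opt) >= eng.log_cond_c(2.0 * c_opt)

    def test_identity_proposal_always_accepted(self, tiny, tiny_cfg):
        """A proposal equal to the current state has acceptance ratio 1:
        the target and proposal terms cancel exactly."""
        eng = _Engine(tiny.X, tiny.Y, tiny_cfg)
        eng.set_state(np.array([0.5, -0.4, 0.7, -0.3]), [0], 3.0)
        from gsgprobit.sampler import _default_proposal

        c_opt, q = _default_proposal(eng)
        log_r = (eng.log_cond_c(eng.c) - eng.log_cond_c(eng.c)) \
            + (q.log_q(eng.c, c_opt, eng.n) - q.log_q(eng.c, c_opt, eng.n))
        assert log_r == 0.0

    def test_stationarity_quick_ks(self, small_synth):
        """Short version of the c-chain vs quadrature check (full-length
        run lives in the acceptance suite)."""
        train, _, _ = small_synth
        cfg = g.ModelConfig(h=100.0, pi=0.1)
        res = g.run_chain(train, cfg, n_iter=300, burn_in=200, thin=10, seed=1)
        st = res.draws[-1]
        eng = _Engine(train.X, train.Y, cfg)
        eng.set_state(st.Z, st.gamma.selected, st.c)
        rng = np.random.default_rng(9)
        c = float(st.c)
        cs = []
        for _ in range(15000):
            eng.c = c
            c, _ = _mh_c_step(eng, rng)
            cs.append(c)
        grid, cdf = helpers.c_conditional_cdf_grid(eng)
        ks = helpers.ks_distance(np.array(cs[1000:]), grid, cdf)
        assert ks < 0.05

    def test_fixed_c_config_rejects_update(self, tiny):
        cfg = g.ModelConfig(h=1.0, pi=0.2, fixed_c=10.0)
        st = g.ChainState(Z=np.array([0.5, -0.4, 0.7, -0.3]),
                          gamma=g.GammaVector(np.zeros(3, dtype=int)), c=10.0)
        with pytest.raises(ValueError):
            g.update_c(st, tiny, cfg, np.random.default_rng(0))


class TestRunChain:
    def test_retained_count_formula(self, tiny, tiny_cfg):
        res = g.run_chain(tiny, tiny_cfg, n_iter=370, burn_in=100, thin=30, seed=0)
        assert res.M == (370 - 100) // 30

    def test_paper_protocol_shape(self):
        """Defaults burn_in=12000 / thin=30 retain 6700 draws from
        12000 + 30 * 6700 iterations (shape check only, no run)."""
        n_iter = 12000 + 30 * 6700
        assert (n_iter - 12000) // 30 == 6700

    def test_seed_reproducibility_bitwise(self, small_synth):
        train, _, _ = small_synth
        cfg = g.ModelConfig(h=100.0, pi=0.1)
        a = g.run_chain(train, cfg, n_iter=400, burn_in=100, thin=3, seed=42)
        b = g.run_chain(train, cfg, n_iter=400, burn_in=100, thin=3, seed=42)
        assert a.M == b.M
        for sa, sb in zip(a.draws, b.draws):
            np.testing.assert_array_equal(sa.gamma.gamma, sb.gamma.gamma)
            np.testing.assert_array_equal(sa.Z, sb.Z)
            assert sa.c == sb.c

    def test_retained_states_satisfy_sign_invariant(self, small_synth):
        train, _, _ = small_synth
        cfg = g.ModelConfig(h=100.0, pi=0.1)
        res = g.run_chain(train, cfg, n_iter=500, burn_in=100, thin=5, seed=3)
        for st in res.draws:
            assert np.all((st.Z > 0) == (train.Y == 1))

    def test_fixed_c_trajectory_constant(self, small_synth):
        train, _, _ = small_synth
        cfg = g.ModelConfig(h=100.0, pi=0.1, fixed_c=10.0)
        res = g.run_chain(train, cfg, n_iter=400, burn_in=100, thin=3, seed=1)
        assert np.all(res.c_values() == 10.0)
        assert res.acceptance_rate_c == 0.0

    def test_fixed_gamma_holds_selection(self, small_synth):
        train, _, _ = small_synth
        cfg = g.ModelConfig(h=100.0, pi=0.1)
        gv = g.GammaVector.from_selected([0, 1, 2], train.p)
        res = g.run_chain(train, cfg, n_iter=300, burn_in=100, thin=5, seed=2,
                          fixed_gamma=gv)
        for st in res.draws:
            np.testing.assert_array_equal(st.gamma.gamma, gv.gamma)

    def test_sparsity_prior_keeps_models_small(self):
        """With pi = 0.005 and 5 strong genes in 100, the average model
        size stays below 15 (pilot-verified bound)."""
        spec = g.SyntheticSpec(n_train=100, n_test=0, p=100,
                               true_support=(0, 1, 2, 3, 4), seed=0)
        train = g.generate(spec)[0]
        cfg = g.ModelConfig(h=100.0, pi=0.005)
        res = g.run_chain(train, cfg, n_iter=1500, burn_in=500, thin=5, seed=4)
        assert res.p_gammas().mean() < 15

    def test_invalid_run_params(self, tiny, tiny_cfg):
        with pytest.raises(ValueError):
            g.run_chain(tiny, tiny_cfg, n_iter=100, burn_in=100, thin=1, seed=0)
        with pytest.raises(ValueError):
            g.run_chain(tiny, tiny_cfg, n_iter=200, burn_in=100, thin=0, seed=0)


class TestJointCorrectness:
    def test_geweke_forward_vs_successive_conditional(self, tiny, tiny_cfg):
        """Forward simulation from the prior + likelihood and the MCMC's
        successive-conditional simulation must agree in distribution.
        Compared via z-scores on moments of (p_gamma, 1/c, Z'Z); the
        reciprocal of c is used because the IG(1/2, n/2) hyperprior has
        no finite mean for c itself.
        """
        X = tiny.X
        n, p = X.shape
        cfg = tiny_cfg
        pi = cfg.pi_vector(p)
        rng = np.random.default_rng(314)
        N = 20000

        def forward_draw():
            c = (0.5 * n) / rng.gamma(0.5)
            gam = (rng.random(p) < pi).astype(int)
            gv = g.GammaVector(gam)
            op = g.build_sigma(gv, c, X, cfg.h)
            L = np.linalg.cholesky(op.dense())
            z = L @ rng.standard_normal(n)
            return gv.p_gamma, 1.0 / c, float(z @ z)

        fwd = np.array([forward_draw() for _ in range(N)])

        # successive-conditional: redraw (Z, Y) from the model given
        # (gamma, c), then one MCMC scan of (gamma, c) given the new Z.
        # The gamma and c full conditionals depend on the data only
        # through Z, so a placeholder Y is immaterial to the kernel.
        sc = np.empty((N, 3))
        c = (0.5 * n) / rng.gamma(0.5)
        gv = g.GammaVector((rng.random(p) < pi).astype(int))
        y_dummy = np.array([1, 0, 1, 0])
        ds_dummy = g.ExpressionDataset(X=X, Y=y_dummy)
        for t in range(N):
            op = g.build_sigma(gv, c, X, cfg.h)
            L = np.linalg.cholesky(op.dense())
            z = L @ rng.standard_normal(n)
            st = g.ChainState(Z=z, gamma=gv, c=c)
            gv = g.update_gamma(st, ds_dummy, cfg, rng)
            eng = _Engine(X, y_dummy, cfg)
            eng.set_state(z, gv.selected, c)
            c, _ = _mh_c_step(eng, rng)
            sc[t] = (gv.p_gamma, 1.0 / c, float(z @ z))

        for j, name in enumerate(["p_gamma", "1/c", "ZtZ"]):
            za = fwd[:, j]
            zb = sc[:, j]
            # conservative autocorrelation inflation for the MCMC stream
            se = math.sqrt(za.var() / N + 20.0 * zb.var() / N)
            zscore = (za.mean() - zb.mean()) / se
            assert abs(zscore) < 4.0, f"{name}: z={zscore:.2f}"
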