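import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtr

import hcfc
from hcfc.gibbs import (
    ChainConfig, PosteriorDraws, truncated_normal, update_factor_cov,
    update_factor_scale, update_factors, update_latent_mlv, update_loadings,
    update_residual_variances, update_thresholds,
)
from hcfc.instrument import InstrumentSpec
from hcfc.model import OrdinalCFAModel, PriorSpec, init_model
from hcfc.synthetic import default_hcfc_truth, generate


def make_model(spec, n, *, mode="probit", loadings=None, factor_cov=None,
               thresholds=None, eta=None, z=None, rng=None):
    """Hand-built model state for unit-testing single updates."""
    J, K, C = spec.n_items, spec.n_factors, spec.n_categories
    return OrdinalCFAModel(
        spec=spec, mode=mode,
        loadings=np.ones(J) if loadings is None else np.asarray(loadings, float),
        residual_var=np.ones(J),
        thresholds=(np.tile(np.linspace(-1, 1, C - 1), (J, 1))
                    if thresholds is None else thresholds),
        factor_cov=np.eye(K) if factor_cov is None else factor_cov,
        eta=np.zeros((n, K)) if eta is None else eta,
        z=np.zeros((n, J)) if z is None else z,
    )


class TestTruncatedNormal:
    @pytest.mark.parametrize("a,b", [(-1.0, 1.0), (0.5, 2.0), (-np.inf, 0.0),
                                     (1.0, np.inf)])
    def test_moments_match_scipy(self, a, b):
        rng = np.random.default_rng(0)
        x = truncated_normal(rng, np.zeros(200_000), 1.0,
                             np.full(200_000, a), np.full(200_000, b))
        ref = stats.truncnorm(a, b)
        assert x.mean() == pytest.approx(ref.mean(), abs=0.01)
        assert x.std() == pytest.approx(ref.std(), abs=0.01)
        assert (x > a).all() and (x <= b + 1e-12).all()

    def test_deep_tail_is_finite_and_inside(self):
        rng = np.random.default_rng(1)
        x = truncated_normal(rng, np.zeros(1000), 1.0,
                             np.full(1000, 8.0), np.full(1000, 9.0))
        assert np.isfinite(x).all()
        assert (x >= 8.0).all() and (x <= 9.0).all()

    def test_location_scale(self):
        rng = np.random.default_rng(2)
        x = truncated_normal(rng, np.full(100_000, 5.0), 2.0,
                             np.full(100_000, -np.inf), np.full(100_000, np.inf))
        assert x.mean() == pytest.approx(5.0, abs=0.03)
        assert x.std() == pytest.approx(2.0, abs=0.03)


@pytest.fixture(scope="module")
def hcfc_table():
    cfg = default_hcfc_truth(seed=100, n_respondents=200, missing_rate=0.05)
    table, _ = generate(cfg)
    return table


class TestUpdateLatentMlv:
    def test_observed_z_in_bracket(self, hcfc_table):
        model = init_model(hcfc_table)
        rng = np.random.default_rng(0)
        update_latent_mlv(model, hcfc_table, rng)
        from hcfc.model import log_joint, model_responses
        assert np.isfinite(log_joint(model, hcfc_table))

    def test_missing_cell_dispersion(self, tiny_spec):
        """Missing-cell draws are untruncated: their sd matches
        sqrt(lam^2 Phi + psi) (closed-form moment, 50k draws, 2%)."""
        n = 50_000
        rng = np.random.default_rng(3)
        lam, phi = 1.5, 0.8
        eta = np.sqrt(phi) * rng.standard_normal((n, 1))
        model = make_model(tiny_spec, n, loadings=[1.0, lam],
                           factor_cov=np.array([[phi]]), eta=eta,
                           thresholds=np.zeros((2, 1)))
        y = pd.DataFrame({"a": [1.0] * n, "b": [np.nan] * n})
        table = hcfc.ResponseTable(responses=y, spec=tiny_spec)
        update_latent_mlv(model, table, rng)
        want = np.sqrt(lam**2 * phi + 1.0)
        assert model.z[:, 1].std() == pytest.approx(want, rel=0.02)

    def test_pooled_z_standard_normal_when_consistent(self, tiny_spec):
        """With zero factor signal and a cut at 0, drawing categories from
        the model and then re-drawing z yields a standard-normal margin."""
        n = 50_000
        rng = np.random.default_rng(4)
        z0 = rng.standard_normal((n, 2))
        y = np.where(z0 > 0, 2.0, 1.0)
        table = hcfc.ResponseTable(
            responses=pd.DataFrame(y, columns=["a", "b"]), spec=tiny_spec)
        model = make_model(tiny_spec, n, factor_cov=np.array([[1e-12]]),
                           thresholds=np.zeros((2, 1)))
        update_latent_mlv(model, table, rng)
        assert model.z[:, 0].mean() == pytest.approx(0.0, abs=0.02)
        assert model.z[:, 0].std() == pytest.approx(1.0, abs=0.02)


class TestUpdateFactors:
    def test_zero_loadings_reproduce_prior(self):
        """With all loadings 0 the conditional is the prior N(0, Phi):
        sample covariance of 50k draws matches Phi within 3%."""
        spec = hcfc.builtin_hcfc8()
        phi = default_hcfc_truth().factor_cov
        n = 50_000
        model = make_model(spec, n, factor_cov=phi.copy(),
                           loadings=np.zeros(spec.n_items))
        rng = np.random.default_rng(5)
        update_factors(model, rng)
        emp = np.cov(model.eta.T)
        assert np.abs(emp - phi).max() < 0.03 * np.abs(phi).max() + 0.01

    def test_tight_residual_concentrates_on_z(self, tiny_spec):
        n = 500
        rng = np.random.default_rng(6)
        z = rng.standard_normal((n, 2))
        model = make_model(tiny_spec, n, z=z)
        model.residual_var = np.array([1e-8, 1e-8])
        update_factors(model, rng)
        # two unit-loading items with tiny noise -> eta ~ their average
        assert np.abs(model.eta[:, 0] - z.mean(axis=1)).max() < 0.01


class TestUpdateLoadings:
    def test_markers_never_move(self, hcfc_table):
        model = init_model(hcfc_table)
        rng = np.random.default_rng(7)
        model.eta = rng.standard_normal(model.eta.shape)
        update_loadings(model, rng)
        assert np.all(model.loadings[model.marker] == 1.0)

    def test_conjugate_regression_recovery(self, tiny_spec):
        """Known factor scores, true loading 2.83, psi=1, n=10,000: the
        conditional posterior mean lands within 0.1 of truth."""
        n = 10_000
        rng = np.random.default_rng(8)
        eta = rng.standard_normal((n, 1))
        z = np.column_stack([eta[:, 0], 2.83 * eta[:, 0]
                             + rng.standard_normal(n)])
        model = make_model(tiny_spec, n, eta=eta, z=z)
        update_loadings(model, rng)
        assert model.loadings[1] == pytest.approx(2.83, abs=0.1)

    def test_tiny_prior_variance_dominates(self, tiny_spec):
        n = 1000
        rng = np.random.default_rng(9)
        eta = rng.standard_normal((n, 1))
        z = np.column_stack([eta[:, 0], 3.0 * eta[:, 0]])
        model = make_model(tiny_spec, n, eta=eta, z=z)
        model.priors = PriorSpec(loading_var=1e-8)
        update_loadings(model, rng)
        assert abs(model.loadings[1]) < 0.01


class TestUpdateResidualVariances:
    def test_probit_mode_fixed(self, hcfc_table):
        model = init_model(hcfc_table, mode="probit")
        update_residual_variances(model, np.random.default_rng(0))
        assert np.all(model.residual_var == 1.0)

    def test_draws_in_bounds_and_consistent(self, tiny_spec):
        """Large n, true psi=1: draws stay in (0,100) and their mean
        matches the untruncated inverse-gamma mean within 5%."""
        n = 20_000
        rng = np.random.default_rng(10)
        eta = rng.standard_normal((n, 1))
        z = np.column_stack([eta[:, 0] + rng.standard_normal(n),
                             eta[:, 0] + rng.standard_normal(n)])
        model = make_model(tiny_spec, n, eta=eta, z=z, mode="paper")
        draws = []
        for _ in range(50):
            update_residual_variances(model, rng)
            draws.append(model.residual_var.copy())
        draws = np.array(draws)
        assert (draws > 0).all() and (draws < 100).all()
        S = ((z - eta) ** 2).sum(axis=0)
        ig_mean = (S / 2) / (n / 2 - 2)  # shape n/2-1, scale S/2
        assert np.abs(draws.mean(axis=0) / ig_mean - 1).max() < 0.05


class TestUpdateFactorCov:
    def test_prior_predictive_precision_identity(self, tiny_spec):
        """With no respondents the Wishart draw is from the prior, whose
        precision mean is the identity (5%, 20k draws)."""
        model = make_model(tiny_spec, 0)
        rng = np.random.default_rng(11)
        precs = []
        for _ in range(20_000):
            update_factor_cov(model, rng)
            precs.append(1.0 / model.factor_cov[0, 0])
        assert np.mean(precs) == pytest.approx(1.0, rel=0.05)

    def test_posterior_consistency_large_n(self):
        spec = hcfc.builtin_hcfc8()
        phi = default_hcfc_truth().factor_cov
        rng = np.random.default_rng(12)
        n = 50_000
        eta = rng.multivariate_normal(np.zeros(8), phi, size=n)
        model = make_model(spec, n, eta=eta)
        update_factor_cov(model, rng)
        assert np.abs(model.factor_cov - phi).max() < 0.03 * np.abs(phi).max()

    def test_every_draw_pd(self, tiny_spec):
        rng = np.random.default_rng(13)
        model = make_model(tiny_spec, 10, eta=rng.standard_normal((10, 1)))
        for _ in range(200):
            update_factor_cov(model, rng)
            np.linalg.cholesky(model.factor_cov)


class TestUpdateThresholds:
    def test_ordering_preserved(self, hcfc_table):
        model = init_model(hcfc_table)
        rng = np.random.default_rng(14)
        for _ in range(30):
            update_latent_mlv(model, hcfc_table, rng)
            update_thresholds(model, hcfc_table, rng)
            assert (np.diff(model.thresholds, axis=1) > 0).all()

    def test_flag_freezes_thresholds(self, hcfc_table):
        cc = ChainConfig(n_iterations=30, burn_in=10, n_chains=1, seed=5,
                         sample_thresholds=False)
        draws = hcfc.run(hcfc_table, config=cc)
        tau = draws.params["thresholds"]
        assert np.ptp(tau, axis=1).max() == 0.0

    def test_binary_cut_recovery_with_known_factor(self, tiny_spec):
        """Binary marker item (loading truly fixed at 1), factor known:
        the sampled cut matches the 1-D grid posterior mean of the probit
        margin within 0.05 (n=20,000, true cut 0.5)."""
        n = 20_000
        rng = np.random.default_rng(15)
        eta = rng.standard_normal((n, 1))
        z_true = eta[:, 0] + rng.standard_normal(n)
        y1 = np.where(z_true > 0.5, 2.0, 1.0)         # marker item "a"
        y2 = np.where(eta[:, 0] + rng.standard_normal(n) > 0.0, 2.0, 1.0)
        table = hcfc.ResponseTable(
            responses=pd.DataFrame({"a": y1, "b": y2}), spec=tiny_spec)
        model = make_model(tiny_spec, n, eta=eta.copy(),
                           thresholds=np.array([[0.0], [0.0]]))
        # profile oracle: flat-prior posterior over the cut on a grid
        grid = np.linspace(0.3, 0.7, 401)
        p2 = 1 - ndtr(grid[:, None] - eta[None, :, 0])
        loglik = np.where(y1[None, :] == 2, np.log(p2), np.log1p(-p2)).sum(axis=1)
        w = np.exp(loglik - loglik.max())
        oracle = float((grid * w).sum() / w.sum())
        draws = []
        for it in range(400):
            update_latent_mlv(model, table, rng)
            update_thresholds(model, table, rng)
            if it >= 100:
                draws.append(model.thresholds[0, 0])
        assert np.mean(draws) == pytest.approx(oracle, abs=0.05)


class TestFactorScaleMove:
    def test_preserves_marker_and_pd(self, hcfc_table):
        model = init_model(hcfc_table)
        rng = np.random.default_rng(16)
        model.eta = rng.standard_normal(model.eta.shape)
        for _ in range(100):
            update_factor_scale(model, rng)
            assert np.all(model.loadings[model.marker] == 1.0)
            np.linalg.cholesky(model.factor_cov)


class TestRun:
    def test_same_seed_identical(self, hcfc_table):
        cc = ChainConfig(n_iterations=40, burn_in=20, n_chains=2, seed=42)
        d1 = hcfc.run(hcfc_table, config=cc)
        d2 = hcfc.run(hcfc_table, config=cc)
        for k in d1.params:
            assert np.array_equal(d1.params[k], d2.params[k])

    @pytest.mark.parametrize("iters,burn,thin,expect", [
        (100, 40, 1, 60), (100, 40, 7, 8), (101, 0, 2, 50)])
    def test_draw_count_arithmetic(self, iters, burn, thin, expect):
        # retained draws = floor((n_iterations - burn_in) / thinning)
        cc = ChainConfig(n_iterations=iters, burn_in=burn, thinning=thin)
        assert cc.n_draws == expect

    def test_log_joint_no_post_burnin_drift(self, hcfc_table):
        """Stationarity smoke test: the post-burn-in log joint shows no
        systematic drift (first/second half means agree within Monte-Carlo
        error)."""
        import arviz as az
        cc = ChainConfig(n_iterations=1200, burn_in=600, n_chains=1, seed=9,
                         save_log_joint=True)
        draws = hcfc.run(hcfc_table, config=cc)
        lj = draws.log_joint[0]
        h1, h2 = lj[:300], lj[300:]
        ess = max(float(az.ess(lj[None, :])), 4.0)
        mcse = lj.std() / np.sqrt(ess)
        assert abs(h1.mean() - h2.mean()) < 6 * mcse

    def test_save_load_round_trip(self, hcfc_table, tmp_path):
        cc = ChainConfig(n_iterations=30, burn_in=10, n_chains=2, seed=1)
        draws = hcfc.run(hcfc_table, config=cc)
        draws.save(tmp_path / "d")
        back = PosteriorDraws.load(tmp_path / "d")
        for k in draws.params:
            assert np.allclose(back.params[k], draws.params[k])
        assert back.spec == draws.spec
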