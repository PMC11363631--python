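"""Threshold-model unit tests: design construction, conjugate updates,
DIC structure and prediction closed forms."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy.special import ndtr
from scipy.stats import norm

import smoltpipe as sp
from smoltpipe.model import (
    Design,
    McmcConfig,
    ModelError,
    ModelSpec,
    PosteriorChain,
    PriorSpec,
    _bernoulli_deviance,
    _draw_beta,
    _sample_liabilities,
    build_design,
    dic,
    gibbs_fit,
    predict_probability,
)
from smoltpipe.simulate import ModelParams, SimConfig


def study(seed=1, n=300, params=None, fam=None, freq=0.5):
    params = params or ModelParams()
    cfg = SimConfig(
        seed=seed,
        n_families_per_cross=fam or {"Wild": 15},
        total_offspring=n,
        founder_freq_L={k: np.full(17, freq) for k in ("wild", "farmed")},
        model_params=params,
    )
    ped = sp.simulate_pedigree(cfg)
    geno = sp.simulate_genotypes(ped, cfg)
    ph = sp.simulate_phenotypes(ped, geno, config=cfg)
    return cfg, ped, ph


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ModelError, match="marginality"):
            ModelSpec(terms=("G:W", "G"))

    def test_removable_interactions_first(self):
        spec = ModelSpec()  # full six-term model
        cands = spec.removable_terms()
        assert cands == ["G:S", "G:W", "W:S"]  # mains locked by interactions

    def test_drop_respects_marginality_chain(self):
        spec = ModelSpec(terms=("G", "W", "G:W"))
        assert spec.removable_terms() == ["G:W"]
        reduced = spec.drop("G:W")
        assert set(reduced.removable_terms()) == {"G", "W"}


class TestBuildDesign:
    def test_intercept_only(self):
        _, ped, ph = study()
        d = build_design(ph, ModelSpec(terms=()), ped)
        assert d.X.shape[1] == 1 and (d.X == 1).all()

    def test_factor_expansion_column_count(self):
        _, ped, ph = study()
        d = build_design(ph, ModelSpec(terms=("G", "W", "G:W"), locus="x"), ped)
        assert d.X.shape[1] == 6  # 1 + 2 + 1 + 2
        assert d.columns == ["(Intercept)", "G[AL]", "G[LL]", "W", "G[AL]:W", "G[LL]:W"]

    def test_weight_centering_stored(self):
        _, ped, ph = study()
        d = build_design(ph, ModelSpec(terms=("W",)), ped)
        assert d.w_center == pytest.approx(ph["W"].mean())
        assert abs(d.X[:, 1].mean()) < 1e-9

    def test_monomorphic_locus_rejected(self):
        _, ped, ph = study()
        ph = ph.copy()
        ph["G"] = "AA"
        with pytest.raises(ModelError, match="inestimable"):
            build_design(ph, ModelSpec(terms=("G",), locus="x"), ped)

    def test_no_call_records_dropped(self):
        _, ped, ph = study()
        ph = ph.copy()
        ph.loc[ph.index[:10], "G"] = "NO_CALL"
        d = build_design(ph, ModelSpec(terms=("G", "W"), locus="x"), ped)
        assert d.n_dropped == 10
        assert d.X.shape[0] == len(ph) - 10


class TestSamplerInternals:
    def test_liability_truncation_signs(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 2, 500)
        y = rng.integers(0, 2, 500).astype(float)
        l = _sample_liabilities(rng, eta, y)
        assert (l[y == 1] > 0).all()
        assert (l[y == 0] <= 0).all()

    def test_liability_far_tail_finite(self):
        rng = np.random.default_rng(1)
        eta = np.array([-12.0, 12.0, -40.0, 40.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        l = _sample_liabilities(rng, eta, y)
        assert np.isfinite(l).all()
        assert (l[0] > 0) and (l[2] > 0) and (l[1] <= 0) and (l[3] <= 0)

    def test_beta_draw_matches_closed_form_posterior(self):
        """Conjugate update oracle: moments of repeated beta draws match
        the closed-form Bayesian linear-regression posterior."""
        rng = np.random.default_rng(2)
        n, p = 200, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        resid = rng.normal(size=n)
        prior_var = 1e4
        prec = X.T @ X + np.eye(p) / prior_var
        chol = scipy.linalg.cho_factor(prec, lower=False)
        mu_exact = np.linalg.solve(prec, X.T @ resid)
        cov_exact = np.linalg.inv(prec)
        draws = np.stack([_draw_beta(rng, chol, X, resid) for _ in range(20_000)])
        assert np.allclose(draws.mean(axis=0), mu_exact, atol=4 * np.sqrt(np.diag(cov_exact) / 20_000) + 1e-3)
        assert np.allclose(np.cov(draws.T), cov_exact, rtol=0.1, atol=1e-4)

    def test_deviance_limits(self):
        y = np.array([1.0, 0.0])
        assert _bernoulli_deviance(y, np.array([40.0, -40.0])) == pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(_bernoulli_deviance(y, np.array([-40.0, 40.0])))


class TestGibbsFit:
    def fit_small(self, seed=3, n=250, params=None, **mcmc_kw):
        params = params or ModelParams(alpha=0.3, beta_W=0.01)
        cfg, ped, ph = study(seed=seed, n=n, params=params)
        d = build_design(ph, ModelSpec(terms=("G", "W"), locus="x"), ped)
        kw = dict(n_iter=800, burn_in=200, thin=2, seed=9, n_chains=2)
        kw.update(mcmc_kw)
        chain = gibbs_fit(d, sp.a_inverse(ped), PriorSpec(), McmcConfig(**kw),
                          store_liabilities=True)
        return d, chain

    def test_draw_count_and_shapes(self):
        d, chain = self.fit_small()
        assert chain.n_draws == 2 * (800 - 200) // 2
        assert chain.beta.shape[1] == len(chain.columns) == 4
        assert (chain.sigma2_a > 0).all()

    def test_all_positive_outcomes_give_positive_liabilities(self):
        cfg, ped, ph = study(seed=4, n=120)
        ph = ph.copy()
        ph["Y"] = 1
        d = build_design(ph, ModelSpec(terms=()), ped)
        chain = gibbs_fit(d, sp.a_inverse(ped), PriorSpec(),
                          McmcConfig(n_iter=400, burn_in=100, thin=1, seed=2, n_chains=1),
                          store_liabilities=True)
        assert (chain.liab > 0).all()

    def test_seed_reproducibility(self):
        _, c1 = self.fit_small(seed=5)
        _, c2 = self.fit_small(seed=5)
        assert np.array_equal(c1.beta, c2.beta)
        assert np.array_equal(c1.sigma2_a, c2.sigma2_a)

    def test_flat_prior_posterior_matches_ml_probit(self):
        """Without the random effect, posterior means approach the ML
        probit estimates (statsmodels oracle) within 3 joint SD."""
        import statsmodels.api as sm

        params = ModelParams(alpha=-1.0, beta_G=(-0.3, -0.7), beta_W=0.01)
        cfg, ped, ph = study(seed=6, n=5000, params=params, fam={"Wild": 250})
        d = build_design(ph, ModelSpec(terms=("G", "W"), locus="x"), ped)
        # ainv=None removes the random effect => plain Bayesian probit
        chain = gibbs_fit(d, None, PriorSpec(),
                          McmcConfig(n_iter=3000, burn_in=500, thin=5, seed=3, n_chains=1))
        ml = sm.Probit(d.y, d.X).fit(disp=0)
        post = chain.summary().set_index("parameter")
        for j, name in enumerate(chain.columns):
            assert abs(post.loc[name, "mean"] - ml.params[j]) < 3 * post.loc[name, "sd"]


class TestDic:
    def test_minimum_draws_enforced(self):
        d, chain = self.make_chain(40)
        with pytest.raises(ModelError, match="200"):
            dic(chain, d)

    @staticmethod
    def make_chain(n_draws, n=50, eta=0.0):
        rng = np.random.default_rng(0)
        y = (rng.random(n) < 0.5).astype(float)
        X = np.ones((n, 1))
        spec = ModelSpec(terms=())
        design = Design(y=y, X=X, columns=["(Intercept)"], z_idx=np.arange(n), q=n, spec=spec)
        beta = np.full((n_draws, 1), eta) + rng.normal(0, 0.01, (n_draws, 1))
        chain = PosteriorChain(
            beta=beta,
            sigma2_a=np.full(n_draws, 0.1),
            deviance=np.array([_bernoulli_deviance(y, X @ b) for b in beta]),
            deviance_liab=np.zeros(n_draws),
            chain_id=np.zeros(n_draws, dtype=int),
            columns=["(Intercept)"],
            spec=spec,
            w_center=0.0,
            geno_levels=("AA", "AL", "LL"),
            a_mean=np.zeros(n),
            liab_mean=np.zeros(n),
        )
        return design, chain

    def test_duplicating_observations_doubles_dbar(self):
        d1, c1 = self.make_chain(300, n=80)
        # duplicate every observation
        y2 = np.concatenate([d1.y, d1.y])
        d2 = Design(y=y2, X=np.ones((160, 1)), columns=["(Intercept)"],
                    z_idx=np.arange(160), q=160, spec=d1.spec)
        c2 = PosteriorChain(
            beta=c1.beta, sigma2_a=c1.sigma2_a,
            deviance=np.array([_bernoulli_deviance(y2, np.ones((160, 1)) @ b) for b in c1.beta]),
            deviance_liab=c1.deviance_liab, chain_id=c1.chain_id, columns=c1.columns,
            spec=c1.spec, w_center=0.0, geno_levels=c1.geno_levels,
            a_mean=np.zeros(160), liab_mean=np.zeros(160),
        )
        assert dic(c2, d2).d_bar == pytest.approx(2 * dic(c1, d1).d_bar, rel=1e-9)

    def test_saturated_fit_deviance_zero(self):
        rng = np.random.default_rng(1)
        n = 60
        y = (rng.random(n) < 0.5).astype(float)
        eta = np.where(y == 1, 50.0, -50.0)
        assert _bernoulli_deviance(y, eta) == pytest.approx(0.0, abs=1e-10)


class TestPredict:
    @staticmethod
    def chain_with_betas(beta_rows, columns, spec, w_center=0.0):
        beta = np.asarray(beta_rows, dtype=float)
        n = beta.shape[0]
        return PosteriorChain(
            beta=beta, sigma2_a=np.ones(n), deviance=np.zeros(n),
            deviance_liab=np.zeros(n), chain_id=np.zeros(n, dtype=int),
            columns=columns, spec=spec, w_center=w_center,
            geno_levels=("AA", "AL", "LL"), a_mean=np.zeros(1), liab_mean=np.zeros(1),
        )

    def test_zero_draws_give_half_probability(self):
        chain = self.chain_with_betas([[0.0]], ["(Intercept)"], ModelSpec(terms=()))
        curve = predict_probability(chain, "AA", [0, 100, 350])
        assert np.allclose(curve["prob"], 0.5)
        assert np.allclose(curve["lo"], 0.5) and np.allclose(curve["hi"], 0.5)

    def test_single_draw_closed_form(self):
        chain = self.chain_with_betas([[1.0]], ["(Intercept)"], ModelSpec(terms=()))
        curve = predict_probability(chain, "AA", [50])
        assert curve["prob"].iloc[0] == pytest.approx(norm.cdf(1.0), abs=1e-12)

    def test_matches_phi_of_eta_exactly_per_draw(self):
        spec = ModelSpec(terms=("G", "W"), locus="x")
        cols = ["(Intercept)", "G[AL]", "G[LL]", "W"]
        rng = np.random.default_rng(2)
        betas = rng.normal(size=(40, 4))
        chain = self.chain_with_betas(betas, cols, spec, w_center=100.0)
        grid = np.array([0.0, 175.0, 350.0])
        for g, (i_al, i_ll) in [("AA", (0, 0)), ("AL", (1, 0)), ("LL", (0, 1))]:
            curve = predict_probability(chain, g, grid)
            eta = (betas[:, 0:1] + i_al * betas[:, 1:2] + i_ll * betas[:, 2:3]
                   + betas[:, 3:4] * (grid - 100.0)[None, :])
            assert np.abs(curve["prob"].to_numpy() - ndtr(eta).mean(axis=0)).max() < 1e-12

    def test_unseen_genotype_refused(self):
        chain = self.chain_with_betas([[0.0]], ["(Intercept)"], ModelSpec(terms=()))
        object.__setattr__  # geno_levels is a plain attribute on the dataclass
        chain.geno_levels = ("AA", "AL")
        with pytest.raises(ModelError, match="absent"):
            predict_probability(chain, "LL", [100])
        with pytest.raises(ModelError, match="unknown"):
            predict_probability(chain, "XX", [100])
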