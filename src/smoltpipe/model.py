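"""Bayesian threshold (liability) animal model for binary smoltification.

The observed status Y_i is a Bernoulli draw through a probit link from a
latent liability

    l_i = x_i' beta + a_i + e_i,      e_i ~ N(0, 1),

where x_i holds an intercept, genotype indicators (AA reference),
weight, sex and their pairwise interactions, and the breeding values
a ~ N(0, A sigma2_a) carry the pedigree correlation through the additive
relationship matrix A.  The residual variance is fixed at 1, which sets
the scale of the threshold model; the additive variance has a scaled
inverse-chi-squared prior and the fixed effects a near-flat normal prior.

Fitting is single-site-free Gibbs sampling with the classic
data-augmentation scheme: liabilities are sampled from truncated
normals, the fixed effects and breeding values from their conjugate
normal full conditionals, and the additive variance from its scaled
inverse-chi-squared full conditional.  The breeding-value update is
performed in the basis of a generalized eigendecomposition of
(Z'Z, A^-1), computed once per dataset, which makes each sweep O(q^2)
and lets backward model selection reuse the factorization across all
candidate fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import log_ndtr, ndtr, ndtri
from scipy.stats import truncnorm

from .diagnostics import effective_sample_size, geweke_z, split_rhat
from .pedigree import Pedigree
from .relatedness import RelationshipMatrix

logger = logging.getLogger(__name__)

TERMS = ("G", "W", "S", "G:W", "G:S", "W:S")
GENOTYPES = ("AA", "AL", "LL")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure: which of G, W, S and their two-way
    interactions enter the liability, with genotype as an unordered
    3-level factor (AA reference) by default."""

    terms: tuple[str, ...] = TERMS
    locus: str | None = None
    genotype_coding: str = "factor"  # "factor" | "additive"

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        for t in self.terms:
            if t not in TERMS:
                raise ModelError(f"unknown model term {t!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ModelError("duplicate model terms")
        for t in self.terms:
            if ":" in t:
                for m in t.split(":"):
                    if m not in self.terms:
                        raise ModelError(
                            f"marginality violation: interaction {t!r} without "
                            f"main effect {m!r}"
                        )
        if self.genotype_coding not in ("factor", "additive"):
            raise ModelError(f"unknown genotype coding {self.genotype_coding!r}")

    def drop(self, term: str) -> "ModelSpec":
        if term not in self.terms:
            raise ModelError(f"term {term!r} not in spec")
        return ModelSpec(
            terms=tuple(t for t in self.terms if t != term),
            locus=self.locus,
            genotype_coding=self.genotype_coding,
        )

    def removable_terms(self) -> list[str]:
        """Terms whose deletion respects marginality, interactions first."""
        locked: set[str] = set()
        for t in self.terms:
            if ":" in t:
                locked.update(t.split(":"))
        cands = [t for t in self.terms if ":" in t or t not in locked]
        return sorted(cands, key=lambda t: (0 if ":" in t else 1, t))


@dataclass(frozen=True)
class PriorSpec:
    """Priors: residual variance is immutably 1; sigma2_a has a scaled
    inverse-chi-squared(nu, s2) prior; fixed effects are N(0, beta_var)."""

    nu: float = 1.0
    s2: float = 1.0
    beta_var: float = 1e8

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.s2 <= 0 or self.beta_var <= 0:
            raise ModelError("prior hyperparameters must be positive")

    @property
    def residual_variance(self) -> float:
        return 1.0


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 60_000
    burn_in: int = 10_000
    thin: int = 25
    seed: int = 0
    n_chains: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ModelError("seed is mandatory")
        if not (0 <= self.burn_in < self.n_iter):
            raise ModelError("require 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ModelError("thin and n_chains must be positive")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class Design:
    """Response, fixed-effect design and random-effect incidence."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    z_idx: np.ndarray  # record -> pedigree position
    q: int  # pedigree size
    spec: ModelSpec
    w_center: float = 0.0
    geno_levels: tuple[str, ...] = GENOTYPES
    n_dropped: int = 0


def _expand_columns(spec: ModelSpec) -> list[str]:
    cols = ["(Intercept)"]
    two_level_g = spec.genotype_coding == "factor"
    g_cols = ["G[AL]", "G[LL]"] if two_level_g else ["G[dose]"]
    for t in spec.terms:
        if t == "G":
            cols += g_cols
        elif t in ("W", "S"):
            cols.append(t)
        elif t == "G:W":
            cols += [f"{g}:W" for g in g_cols]
        elif t == "G:S":
            cols += [f"{g}:S" for g in g_cols]
        elif t == "W:S":
            cols.append("W:S")
    return cols


def _design_rows(
    spec: ModelSpec, g: np.ndarray, w_centered: np.ndarray, s: np.ndarray
) -> np.ndarray:
    """Assemble X for genotype strings g, centered weight and sex arrays."""
    n = len(w_centered)
    parts = [np.ones(n)]
    if spec.genotype_coding == "factor":
        gvars = [(g == "AL").astype(float), (g == "LL").astype(float)]
    else:
        gvars = [np.array([GENOTYPES.index(x) for x in g], dtype=float)]
    for t in spec.terms:
        if t == "G":
            parts += gvars
        elif t == "W":
            parts.append(w_centered)
        elif t == "S":
            parts.append(s)
        elif t == "G:W":
            parts += [gv * w_centered for gv in gvars]
        elif t == "G:S":
            parts += [gv * s for gv in gvars]
        elif t == "W:S":
            parts.append(w_centered * s)
    return np.column_stack(parts)


def build_design(records: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> Design:
    """Build (Y, X, Z) from a phenotype table joined to genotypes.

    ``records`` needs columns ``id, Y, W, S`` and, when G enters the
    model, ``G`` with values AA/AL/LL (missing or NO_CALL rows are
    dropped with a logged count).  Weight is centered internally for
    conditioning; the center is kept for prediction.
    """
    needs_g = any(t == "G" or "G" in t.split(":") for t in spec.terms)
    df = records.copy()
    n0 = len(df)
    if needs_g:
        if "G" not in df.columns:
            raise ModelError("spec includes G but records have no 'G' column")
        ok = df["G"].isin(GENOTYPES)
        df = df[ok]
        if len(df) < n0:
            logger.info("dropped %d records with missing/NO_CALL genotype", n0 - len(df))
        levels = tuple(sorted(set(df["G"]), key=GENOTYPES.index))
        if len(levels) < 2:
            raise ModelError(
                f"genotype effect inestimable: only {levels} observed at locus "
                f"{spec.locus!r}"
            )
    else:
        levels = GENOTYPES

    for col in ("Y", "W", "S"):
        if col not in df.columns:
            raise ModelError(f"records lack required column {col!r}")
        if df[col].isna().any():
            raise ModelError(f"missing values in column {col!r}")

    y = df["Y"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ModelError("Y must be binary 0/1")
    w = df["W"].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ModelError("weights must be positive")
    w_center = float(w.mean())
    s = df["S"].to_numpy(dtype=float)
    g = df["G"].to_numpy(dtype=object) if "G" in df.columns else np.array(["AA"] * len(df))

    X = _design_rows(spec, g, w - w_center, s)
    z_idx = ped.index_of(df["id"])
    return Design(
        y=y,
        X=X,
        columns=_expand_columns(spec),
        z_idx=z_idx,
        q=ped.n,
        spec=spec,
        w_center=w_center,
        geno_levels=levels,
        n_dropped=n0 - len(df),
    )


@dataclass
class RandomEffectOperator:
    """Generalized eigendecomposition of (Z'Z, A^-1).

    With V such that V' A^-1 V = I and V' Z'Z V = diag(w), the
    breeding-value full-conditional precision Z'Z + A^-1/sigma2_a
    becomes diag(w + 1/sigma2_a) in the V basis, so exact conjugate
    draws cost two dense mat-vecs per sweep.
    """

    V: np.ndarray
    w: np.ndarray
    q: int

    @classmethod
    def build(cls, z_idx: np.ndarray, ainv: np.ndarray | RelationshipMatrix) -> "RandomEffectOperator":
        K = ainv.values if isinstance(ainv, RelationshipMatrix) else np.asarray(ainv, float)
        q = K.shape[0]
        m = np.bincount(z_idx, minlength=q).astype(float)
        try:
            w, V = scipy.linalg.eigh(np.diag(m), K)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise ModelError(f"A-inverse is not positive definite: {exc}") from exc
        return cls(V=V, w=np.clip(w, 0.0, None), q=q)


@dataclass
class PosteriorChain:
    """Retained MCMC draws and enough state for DIC and prediction."""

    beta: np.ndarray  # (n_draws_total, p)
    sigma2_a: np.ndarray
    deviance: np.ndarray  # conditional Bernoulli deviance per draw
    deviance_liab: np.ndarray  # Gaussian deviance of the liabilities
    chain_id: np.ndarray
    columns: list[str]
    spec: ModelSpec
    w_center: float
    geno_levels: tuple[str, ...]
    a_mean: np.ndarray
    liab_mean: np.ndarray
    a: np.ndarray | None = None  # (n_draws_total, q) when stored
    liab: np.ndarray | None = None  # (n_draws_total, n) when stored
    n_chains: int = 1

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def summary(self) -> pd.DataFrame:
        names = list(self.columns) + ["sigma2_a"]
        draws = np.column_stack([self.beta, self.sigma2_a])
        return pd.DataFrame(
            {
                "parameter": names,
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0, ddof=1),
                "q2.5": np.percentile(draws, 2.5, axis=0),
                "q97.5": np.percentile(draws, 97.5, axis=0),
            }
        )

    def diagnostics(self) -> pd.DataFrame:
        rows = []
        per_chain = np.array_split(np.arange(self.n_draws), self.n_chains)
        names = list(self.columns) + ["sigma2_a"]
        draws = np.column_stack([self.beta, self.sigma2_a])
        for j, name in enumerate(names):
            x = draws[:, j]
            ess = sum(effective_sample_size(x[idx]) for idx in per_chain)
            gz = geweke_z(x[per_chain[0]])
            if self.n_chains >= 2:
                width = min(len(idx) for idx in per_chain)
                rhat = split_rhat(np.stack([x[idx[:width]] for idx in per_chain]))
            else:
                rhat = float("nan")
            rows.append((name, ess, gz, rhat))
        return pd.DataFrame(rows, columns=["parameter", "ess", "geweke_z", "split_rhat"])


def _sample_liabilities(
    rng: np.random.Generator, eta: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Truncated-normal liability draws: l > 0 where y = 1, l <= 0 otherwise."""
    u = rng.random(eta.size)
    p0 = ndtr(-eta)  # prior mass below the threshold
    p = np.where(y == 1.0, p0 + u * (1.0 - p0), u * p0)
    l = eta + ndtri(np.clip(p, 1e-300, 1.0 - 1e-16))
    # far-tail cases where the interval mass underflows in double precision;
    # reuse the same uniforms so the stream consumption stays fixed
    bad = ~np.isfinite(l) | np.where(y == 1.0, 1.0 - p0 < 1e-14, p0 < 1e-14)
    if bad.any():
        idx = np.nonzero(bad)[0]
        lo = np.where(y[idx] == 1.0, -eta[idx], -np.inf)
        hi = np.where(y[idx] == 1.0, np.inf, -eta[idx])
        l[idx] = truncnorm.ppf(u[idx], lo, hi, loc=eta[idx], scale=1.0)
    pos = y == 1.0
    l[pos] = np.maximum(l[pos], 1e-12)
    l[~pos] = np.minimum(l[~pos], 0.0)
    return l


def _draw_beta(
    rng: np.random.Generator,
    chol_prec: tuple[np.ndarray, bool],
    X: np.ndarray,
    resid: np.ndarray,
) -> np.ndarray:
    """Conjugate N(P^-1 X'r, P^-1) draw given precision Cholesky of P."""
    mu = scipy.linalg.cho_solve(chol_prec, X.T @ resid)
    c, _ = chol_prec
    noise = scipy.linalg.solve_triangular(c, rng.standard_normal(len(mu)), lower=False)
    return mu + noise


def _bernoulli_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """-2 log-likelihood through the probit link, tail-stable."""
    return float(-2.0 * np.sum(np.where(y == 1.0, log_ndtr(eta), log_ndtr(-eta))))


def gibbs_fit(
    design: Design,
    ainv: RelationshipMatrix | np.ndarray | None,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    operator: RandomEffectOperator | None = None,
    store_liabilities: bool = False,
    store_effects: bool = False,
) -> PosteriorChain:
    """Gibbs-sample the threshold animal model.

    Each sweep draws (i) liabilities from truncated normals around the
    current linear predictor, (ii) fixed effects from their conjugate
    normal update, (iii) breeding values from the mixed-model update
    with precision Z'Z + A^-1/sigma2_a, and (iv) sigma2_a from a scaled
    inverse-chi-squared; the residual variance stays fixed at 1.

    ``ainv=None`` drops the pedigree random effect entirely (plain
    Bayesian probit regression; sigma2_a is reported as zero).
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y, X, z_idx = design.y, design.X, design.z_idx
    n, p = X.shape
    with_re = ainv is not None or operator is not None
    if with_re and operator is None:
        operator = RandomEffectOperator.build(z_idx, ainv)
    q = operator.q if with_re else design.q

    prec_beta = X.T @ X + np.eye(p) / prior.beta_var
    try:
        chol_prec = scipy.linalg.cho_factor(prec_beta, lower=False)
    except scipy.linalg.LinAlgError as exc:
        raise ModelError(f"singular fixed-effect precision ({exc}); check design") from exc

    # One RNG stream per update type: the liability, breeding-value and
    # variance streams then consume the same deviates regardless of the
    # fixed-effect dimension, so fits of nested specs under one seed are
    # coupled (common random numbers) and their DIC difference is a
    # paired, low-variance comparison.
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    n_keep = mcmc.n_draws_per_chain
    total = n_keep * mcmc.n_chains

    beta_out = np.empty((total, p))
    s2a_out = np.empty(total)
    dev_out = np.empty(total)
    devl_out = np.empty(total)
    chain_out = np.empty(total, dtype=int)
    a_out = np.empty((total, q)) if store_effects else None
    l_out = np.empty((total, n)) if store_liabilities else None
    a_sum = np.zeros(q)
    l_sum = np.zeros(n)

    if with_re:
        V, w = operator.V, operator.w
    k = 0
    for c, seed in enumerate(seeds):
        rng_l, rng_beta, rng_a, rng_s2 = (np.random.default_rng(s) for s in seed.spawn(4))
        beta = np.zeros(p)
        a = np.zeros(q)
        s2a = prior.s2 if with_re else 0.0
        u_coord = np.zeros(q)
        for it in range(mcmc.n_iter):
            eta = X @ beta + a[z_idx]
            l = _sample_liabilities(rng_l, eta, y)
            beta = _draw_beta(rng_beta, chol_prec, X, l - a[z_idx])
            if with_re:
                # breeding values in the eigenbasis
                r = np.bincount(z_idx, weights=l - X @ beta, minlength=q)
                t = V.T @ r
                denom = w + 1.0 / max(s2a, 1e-12)
                u_coord = t / denom + rng_a.standard_normal(q) / np.sqrt(denom)
                a = V @ u_coord
                # u'u equals a' A^-1 a in the eigenbasis
                quad = float(u_coord @ u_coord)
                s2a = (prior.nu * prior.s2 + quad) / rng_s2.chisquare(prior.nu + q)
            if not np.isfinite(s2a) or not np.all(np.isfinite(beta)):
                raise ModelError(f"non-finite update at iteration {it}; aborting")
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                eta_full = X @ beta + a[z_idx]
                beta_out[k] = beta
                s2a_out[k] = s2a
                dev_out[k] = _bernoulli_deviance(y, eta_full)
                devl_out[k] = n * np.log(2 * np.pi) + float(np.sum((l - eta_full) ** 2))
                chain_out[k] = c
                a_sum += a
                l_sum += l
                if a_out is not None:
                    a_out[k] = a
                if l_out is not None:
                    l_out[k] = l
                k += 1

    chain = PosteriorChain(
        beta=beta_out[:k],
        sigma2_a=s2a_out[:k],
        deviance=dev_out[:k],
        deviance_liab=devl_out[:k],
        chain_id=chain_out[:k],
        columns=list(design.columns),
        spec=design.spec,
        w_center=design.w_center,
        geno_levels=design.geno_levels,
        a_mean=a_sum / max(k, 1),
        liab_mean=l_sum / max(k, 1),
        a=a_out[:k] if a_out is not None else None,
        liab=l_out[:k] if l_out is not None else None,
        n_chains=mcmc.n_chains,
    )
    ess = chain.diagnostics().set_index("parameter")["ess"].drop("sigma2_a")
    low = ess[ess < 100]
    if len(low):
        warnings.warn(
            f"poor mixing: effective sample size < 100 for {list(low.index)}",
            RuntimeWarning,
            stacklevel=2,
        )
    return chain


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    d_bar: float
    d_hat: float


def dic(chain: PosteriorChain, design: Design, on_liability: bool = False) -> DicResult:
    """Deviance information criterion from a fitted chain.

    Default convention: the conditional-on-(beta, a) Bernoulli deviance
    with the latent liabilities integrated out through the link.
    ``on_liability=True`` switches to the Gaussian deviance of the
    augmented liabilities (plug-in at their posterior means).
    """
    if chain.n_draws < 200:
        raise ModelError("DIC needs at least 200 retained draws")
    eta_hat = design.X @ chain.beta.mean(axis=0) + chain.a_mean[design.z_idx]
    if on_liability:
        d_bar = float(chain.deviance_liab.mean())
        n = design.X.shape[0]
        d_hat = n * np.log(2 * np.pi) + float(np.sum((chain.liab_mean - eta_hat) ** 2))
    else:
        d_bar = float(chain.deviance.mean())
        d_hat = _bernoulli_deviance(design.y, eta_hat)
    p_d = d_bar - d_hat
    return DicResult(dic=d_bar + p_d, p_d=p_d, d_bar=d_bar, d_hat=d_hat)


def predict_probability(
    chain: PosteriorChain,
    genotype: str,
    weights: Sequence[float] | np.ndarray,
    sex: float = 0.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior predicted probability of smoltification vs weight.

    Per grid point the probability is averaged over draws of
    Phi(x(g, w, s)' beta) with the breeding value marginalized at zero;
    the band holds the (1 - level)/2 posterior percentiles.
    """
    if genotype not in GENOTYPES:
        raise ModelError(f"unknown genotype {genotype!r}")
    if genotype not in chain.geno_levels:
        raise ModelError(
            f"genotype {genotype!r} absent from the training data "
            f"(observed: {chain.geno_levels}); refusing to extrapolate"
        )
    wgrid = np.asarray(weights, dtype=float)
    g = np.array([genotype] * wgrid.size, dtype=object)
    s = np.full(wgrid.size, float(sex))
    Xg = _design_rows(chain.spec, g, wgrid - chain.w_center, s)
    eta = chain.beta @ Xg.T  # (draws, grid)
    prob = ndtr(eta)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    return pd.DataFrame(
        {
            "genotype": genotype,
            "sex": float(sex),
            "weight": wgrid,
            "prob": prob.mean(axis=0),
            "lo": np.percentile(prob, lo, axis=0),
            "hi": np.percentile(prob, hi, axis=0),
        }
    )
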