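"""BayesR: Gibbs sampling for the four-component normal-mixture model.

SNP effects epsilon_j follow the mixture

    epsilon_j ~ pi_1 N(0, 0) + pi_2 N(0, 1e-4 sigma2_g)
              + pi_3 N(0, 1e-3 sigma2_g) + pi_4 N(0, 1e-2 sigma2_g)

with the component variances tied to the current additive-variance draw
sigma2_g each iteration, mixing proportions pi given a Dirichlet prior,
and sigma2_g / sigma2_e given scaled inverse-chi-square priors.  Fixed
effects are pre-absorbed by projecting the phenotype and the (centered)
genotype design onto the covariate-orthogonal space, leaving a
residual-update single-site Gibbs sweep over SNPs that is compiled with
numba.  The chain is reproducible for a fixed seed.

Posterior summaries: per-SNP posterior-mean effects, per-SNP component
occupancies, and per-component P_num (fraction of SNPs assigned) and
P_var (share of the genetic variance sum_j 2 p_j (1 - p_j) eps_j^2, the
null component contributing zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .gblup import PredictionResult
from .genotype import GenotypeMatrix, PhenotypeTable, compute_maf, impute_mean

__all__ = [
    "BayesRConfig",
    "BayesRPosterior",
    "MixtureSummary",
    "bayesr_fit",
    "bayesr_predict",
    "summarize_mixture",
]


@dataclass(frozen=True)
class BayesRConfig:
    """Chain settings for the BayesR Gibbs sampler."""

    seed: int
    multipliers: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    iterations: int = 10_000
    burnin: int = 2_500
    thinning: int = 10
    dirichlet_alpha: float = 1.0
    prior_df: float = 4.0

    def __post_init__(self) -> None:
        if self.multipliers[0] != 0.0 or list(self.multipliers) != sorted(self.multipliers):
            raise ValueError("multipliers must be ascending with a leading 0")
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("need burnin < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class BayesRPosterior:
    """Posterior summaries and thinned draws from one BayesR chain."""

    effect_mean: np.ndarray          # (m,) posterior-mean SNP effects
    occupancy: np.ndarray            # (m, K) posterior component probabilities
    sigma2_g_draws: np.ndarray
    sigma2_e_draws: np.ndarray
    genetic_var_draws: np.ndarray    # per-draw Var of fitted genetic values
    pi_draws: np.ndarray             # (draws, K)
    pvar_draws: np.ndarray           # (draws, K) per-draw variance shares
    var_weights: np.ndarray          # (m,) 2 p (1 - p) per SNP
    train_means: np.ndarray          # (m,) training dosage means (for centering)
    vids: list[str]
    config: BayesRConfig

    def __post_init__(self) -> None:
        if not np.allclose(self.occupancy.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("occupancy probabilities must sum to 1 per SNP")
        if not np.allclose(self.pi_draws.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mixture proportions must sum to 1 per draw")

    @property
    def n_draws(self) -> int:
        return len(self.sigma2_g_draws)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp": self.vids, "mean_effect": self.effect_mean})
        for k in range(self.occupancy.shape[1]):
            df[f"p_comp{k + 1}"] = self.occupancy[:, k]
        return df


@dataclass
class MixtureSummary:
    """Per-component P_num and P_var (fractions, summing to 1)."""

    p_num: np.ndarray
    p_var: np.ndarray
    multipliers: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)


@njit(cache=True)
def _gibbs(zt, y, zz, w, gammas, n_iter, burnin, thin, alpha, nu_g, s0_g,
           nu_e, s0_e, seed,
           beta_sum, occ, sg_draws, se_draws, gvar_draws, pi_draws, pvar_draws):
    np.random.seed(seed)
    m, n = zt.shape
    nk = gammas.shape[0]
    beta = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    pi = np.full(nk, 1.0 / nk)
    sg = s0_g
    se = s0_e
    e = y.copy()
    logl = np.empty(nk)
    counts = np.empty(nk)
    kept = 0
    for it in range(n_iter):
        for j in range(m):
            old = beta[j]
            if old != 0.0:
                for i in range(n):
                    e[i] += zt[j, i] * old
            rhs = 0.0
            for i in range(n):
                rhs += zt[j, i] * e[i]
            for k in range(nk):
                if gammas[k] == 0.0:
                    logl[k] = np.log(pi[k] + 1e-300)
                else:
                    tau = gammas[k] * sg
                    denom = se + tau * zz[j]
                    logl[k] = (np.log(pi[k] + 1e-300)
                               + 0.5 * np.log(se / denom)
                               + 0.5 * rhs * rhs * tau / (se * denom))
            mx = logl[0]
            for k in range(1, nk):
                if logl[k] > mx:
                    mx = logl[k]
            tot = 0.0
            for k in range(nk):
                logl[k] = np.exp(logl[k] - mx)
                tot += logl[k]
            u = np.random.random() * tot
            acc = 0.0
            knew = nk - 1
            for k in range(nk):
                acc += logl[k]
                if u <= acc:
                    knew = k
                    break
            comp[j] = knew
            if gammas[knew] == 0.0:
                beta[j] = 0.0
            else:
                tau = gammas[knew] * sg
                prec = zz[j] / se + 1.0 / tau
                mean = (rhs / se) / prec
                b = mean + np.random.normal(0.0, 1.0) / np.sqrt(prec)
                beta[j] = b
                for i in range(n):
                    e[i] -= zt[j, i] * b
        # mixture proportions: Dirichlet via normalized gammas
        for k in range(nk):
            counts[k] = alpha
        for j in range(m):
            counts[comp[j]] += 1.0
        tot = 0.0
        for k in range(nk):
            counts[k] = np.random.gamma(counts[k], 1.0)
            tot += counts[k]
        for k in range(nk):
            pi[k] = counts[k] / tot
        # additive-variance scale from non-null effects
        ssq = 0.0
        n_nz = 0
        for j in range(m):
            if comp[j] > 0:
                ssq += beta[j] * beta[j] / gammas[comp[j]]
                n_nz += 1
        chi = 2.0 * np.random.gamma(0.5 * (nu_g + n_nz), 1.0)
        sg = (nu_g * s0_g + ssq) / max(chi, 1e-12)
        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        chi = 2.0 * np.random.gamma(0.5 * (nu_e + n), 1.0)
        se = (nu_e * s0_e + sse) / max(chi, 1e-12)
        if not (np.isfinite(sg) and np.isfinite(se)):
            return -(it + 1)
        if it >= burnin and (it - burnin) % thin == 0:
            sg_draws[kept] = sg
            se_draws[kept] = se
            # realized genetic variance of the current draw: g = y - e
            gm_ = 0.0
            for i in range(n):
                gm_ += y[i] - e[i]
            gm_ /= n
            gv = 0.0
            for i in range(n):
                d = (y[i] - e[i]) - gm_
                gv += d * d
            gvar_draws[kept] = gv / n
            share_tot = 0.0
            for k in range(nk):
                pi_draws[kept, k] = pi[k]
                pvar_draws[kept, k] = 0.0
            for j in range(m):
                beta_sum[j] += beta[j]
                occ[j, comp[j]] += 1.0
                if comp[j] > 0:
                    v = w[j] * beta[j] * beta[j]
                    pvar_draws[kept, comp[j]] += v
                    share_tot += v
            if share_tot > 0.0:
                for k in range(nk):
                    pvar_draws[kept, k] /= share_tot
            kept += 1
    return kept


def bayesr_fit(gm: GenotypeMatrix, pheno: PhenotypeTable,
               cfg: BayesRConfig) -> BayesRPosterior:
    """Run one BayesR Gibbs chain and return posterior summaries."""
    if pheno.samples != list(gm.samples):
        raise ValueError("samples misaligned between genotypes and phenotypes")
    if gm.n_snps < 1:
        raise ValueError("need at least one SNP")
    x_dos = impute_mean(gm.dosage)
    train_means = x_dos.mean(axis=0)
    z = x_dos - train_means
    # pre-absorb fixed effects: project onto the covariate-orthogonal space
    x = pheno.design_matrix()
    xtx_inv = np.linalg.pinv(x.T @ x)
    proj = lambda a: a - x @ (xtx_inv @ (x.T @ a))
    y = proj(pheno.y)
    z = proj(z)

    maf = compute_maf(gm)
    p = np.where(np.isnan(maf), 0.0, np.nansum(gm.dosage, axis=0)
                 / (2.0 * np.maximum(np.sum(~np.isnan(gm.dosage), axis=0), 1)))
    w = 2.0 * p * (1.0 - p)

    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    nu = cfg.prior_df
    s0_g = 0.5 * var_y * (nu - 2.0) / nu   # prior mean sigma2_g = Var(y)/2
    s0_e = 0.5 * var_y * (nu - 2.0) / nu

    n_kept = (cfg.iterations - cfg.burnin + cfg.thinning - 1) // cfg.thinning
    nk = len(cfg.multipliers)
    m = gm.n_snps
    beta_sum = np.zeros(m)
    occ = np.zeros((m, nk))
    sg_draws = np.zeros(n_kept)
    se_draws = np.zeros(n_kept)
    gvar_draws = np.zeros(n_kept)
    pi_draws = np.zeros((n_kept, nk))
    pvar_draws = np.zeros((n_kept, nk))
    zt = np.ascontiguousarray(z.T)
    zz = np.einsum("ji,ji->j", zt, zt)
    ret = _gibbs(zt, y, zz, w, np.asarray(cfg.multipliers, dtype=np.float64),
                 cfg.iterations, cfg.burnin, cfg.thinning, cfg.dirichlet_alpha,
                 nu, s0_g, nu, s0_e, cfg.seed % (2 ** 31),
                 beta_sum, occ, sg_draws, se_draws, gvar_draws, pi_draws,
                 pvar_draws)
    if ret < 0:
        raise RuntimeError(f"BayesR chain produced non-finite values at iteration {-ret}")
    kept = int(ret)
    if kept < 1:
        raise RuntimeError("BayesR chain retained no draws")
    return BayesRPosterior(
        effect_mean=beta_sum / kept,
        occupancy=occ[:, :] / kept,
        sigma2_g_draws=sg_draws[:kept],
        sigma2_e_draws=se_draws[:kept],
        genetic_var_draws=gvar_draws[:kept],
        pi_draws=pi_draws[:kept],
        pvar_draws=pvar_draws[:kept],
        var_weights=w,
        train_means=train_means,
        vids=gm.variants["vid"].tolist(),
        config=cfg,
    )


def bayesr_predict(post: BayesRPosterior, gm_validation: GenotypeMatrix,
                   panel_label: str = "") -> PredictionResult:
    """GEBV = centered validation dosage x posterior-mean effects.

    Validation dosages are centered at the training means stored in the
    posterior so train/validation predictions share one origin.
    """
    val_ids = gm_validation.variants["vid"].tolist()
    if val_ids != post.vids:
        offend = [v for v in val_ids if v not in set(post.vids)][:5]
        raise ValueError(f"SNP sets misaligned between posterior and validation "
                         f"matrix; e.g. {offend or 'ordering differs'}")
    z = impute_mean(gm_validation.dosage) - post.train_means
    gebv = z @ post.effect_mean
    return PredictionResult(list(gm_validation.samples), gebv,
                            model="bayesr", panel=panel_label)


def summarize_mixture(post: BayesRPosterior) -> MixtureSummary:
    """Posterior-mean P_num and P_var per mixture component."""
    if post.n_draws < 1:
        raise ValueError("posterior has no retained draws")
    p_num = post.occupancy.mean(axis=0)
    p_var = post.pvar_draws.mean(axis=0)
    return MixtureSummary(p_num=p_num, p_var=p_var,
                          multipliers=post.config.multipliers)
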