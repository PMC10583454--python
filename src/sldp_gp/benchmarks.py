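"""Reproducible desk-scale benchmark experiments.

These functions re-run the package's core claims under fixed simulated
study conditions: REML heritability recovery, type-I error calibration
of the association scan, the SLDP gain for traits driven by few QTN (and
its absence under a near-infinitesimal architecture), and the
BayesR-versus-GBLUP accuracy comparison.  Defaults are the simulation
conditions used throughout the package's validation; each function is
deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .bayesr import BayesRConfig, bayesr_fit, bayesr_predict
from .evaluate import accuracy
from .gblup import build_grm, gblup_predict, reml_fit
from .genotype import PhenotypeTable
from .gwas import mlma_scan
from .ld import PruneConfig, sldp_prune, _standardized
from .simulate import GenoSimConfig, simulate_genotypes, simulate_trait

__all__ = [
    "heritability_recovery",
    "gwas_type1_error",
    "sldp_qtn_experiment",
    "bayesr_vs_gblup",
]


def heritability_recovery(h2: float, n_reps: int = 20, n: int = 1000,
                          m: int = 5000, n_qtn: int = 100,
                          seed: int = 0) -> float:
    """Mean REML heritability estimate over replicate simulated traits."""
    ests = []
    for rep in range(n_reps):
        gm = simulate_genotypes(GenoSimConfig(
            n_individuals=n, n_snps=m, seed=seed * 1009 + rep,
            chromosomes=5, ld_decay=0.9))
        pheno, _ = simulate_trait(gm, n_qtn, h2, seed=seed * 2003 + rep)
        ests.append(reml_fit(pheno, build_grm(gm)).h2)
    return float(np.mean(ests))


def gwas_type1_error(n_sims: int = 500, n: int = 300, m: int = 200,
                     alpha: float = 0.05, seed: int = 0
                     ) -> tuple[float, np.ndarray]:
    """Empirical rejection rate of the MLM scan on permuted noise.

    One low-LD panel is scanned against ``n_sims`` permutations of a
    noise phenotype; returns the pooled rejection fraction at ``alpha``
    and the pooled P-values.
    """
    gm = simulate_genotypes(GenoSimConfig(n_individuals=n, n_snps=m,
                                          seed=seed + 77, chromosomes=4,
                                          ld_decay=0.2))
    grm = build_grm(gm)
    rng = np.random.default_rng(seed + 177)
    y0 = rng.standard_normal(n)
    rej = tot = 0
    pvals = []
    for _ in range(n_sims):
        pheno = PhenotypeTable(list(gm.samples), rng.permutation(y0))
        res = mlma_scan(gm, pheno, grm)
        pvals.append(res.p[res.tested])
        rej += int(np.sum(res.p[res.tested] < alpha))
        tot += int(res.tested.sum())
    return rej / tot, np.concatenate(pvals)


def _qtn_important_set(gm, truth, r2_link: float = 0.90) -> np.ndarray:
    """SLDP_QTN important set: the QTN plus their r^2 > r2_link partners."""
    z = _standardized(gm)
    n = gm.n_samples
    mask = np.zeros(gm.n_snps, dtype=bool)
    mask[truth.qtn_indices] = True
    for q in truth.qtn_indices:
        r2 = (z.T @ z[:, q] / n) ** 2
        mask |= r2 > r2_link
    return np.flatnonzero(mask)


def sldp_qtn_experiment(n_reps: int = 10, n_qtn: int = 100, h2: float = 0.30,
                        n: int = 800, m: int = 2500, n_train: int = 600,
                        r2_grid: tuple[float, ...] = (0.10, 0.50, 0.90),
                        seed: int = 0) -> list[tuple[float, float]]:
    """Validation accuracy of the full panel versus the SLDP_QTN panel.

    Per replicate: simulate genotypes and an additive trait, build the
    truth-based important set (QTN and their high-LD partners), select
    the pruning r^2 threshold by five-fold cross-validation in the
    training population (the per-trait parameter-optimization protocol),
    then train GBLUP on the ``n_train`` individuals and evaluate accuracy
    against TBV in the held-out remainder.  Returns (full, sldp)
    accuracy pairs.
    """
    from .evaluate import kfold_cv

    out = []
    for rep in range(n_reps):
        gm = simulate_genotypes(GenoSimConfig(
            n_individuals=n, n_snps=m, seed=seed * 5001 + rep,
            chromosomes=5, ld_decay=0.9))
        pheno, truth = simulate_trait(gm, n_qtn, h2, seed=seed * 6007 + rep)
        trn = np.arange(n_train)
        val = np.arange(n_train, n)
        trn_ids = [gm.samples[i] for i in trn]
        ph_trn = pheno.reindex(trn_ids)
        val_ids = [gm.samples[i] for i in val]
        important = _qtn_important_set(gm, truth)
        gm_trn = gm.subset(samples=trn)
        best_r2, best_cv = None, -np.inf
        for r2_thr in r2_grid:
            panel = sldp_prune(gm, important, PruneConfig(r2_thr))
            cv_acc, _ = kfold_cv(gm_trn, ph_trn, panel=panel, k=5,
                                 seed=seed * 401 + rep,
                                 target=truth.tbv[trn])
            if cv_acc > best_cv:
                best_r2, best_cv = r2_thr, cv_acc
        panel = sldp_prune(gm, important, PruneConfig(best_r2))
        accs = []
        for sub in (gm, gm.subset(snps=panel.kept)):
            pred = gblup_predict(ph_trn, build_grm(sub), val_ids)
            accs.append(accuracy(pred.gebv, truth.tbv[val]))
        out.append((accs[0], accs[1]))
    return out


def bayesr_vs_gblup(n_reps: int = 10, n_qtn: int = 100, h2: float = 0.50,
                    n: int = 800, m: int = 2000, n_train: int = 600,
                    seed: int = 0, chain=(2000, 500, 5)
                    ) -> list[tuple[float, float]]:
    """Validation accuracy of GBLUP versus BayesR on the same replicates."""
    iters, burnin, thin = chain
    out = []
    for rep in range(n_reps):
        gm = simulate_genotypes(GenoSimConfig(
            n_individuals=n, n_snps=m, seed=seed * 7001 + rep,
            chromosomes=4, ld_decay=0.9))
        pheno, truth = simulate_trait(gm, n_qtn, h2, seed=seed * 8009 + rep)
        trn = np.arange(n_train)
        val = np.arange(n_train, n)
        ph_trn = pheno.reindex([gm.samples[i] for i in trn])
        val_ids = [gm.samples[i] for i in val]
        pred_g = gblup_predict(ph_trn, build_grm(gm), val_ids)
        acc_g = accuracy(pred_g.gebv, truth.tbv[val])
        post = bayesr_fit(gm.subset(samples=trn), ph_trn,
                          BayesRConfig(seed=seed * 9013 + rep,
                                       iterations=iters, burnin=burnin,
                                       thinning=thin))
        pred_b = bayesr_predict(post, gm.subset(samples=val))
        acc_b = accuracy(pred_b.gebv, truth.tbv[val])
        out.append((acc_g, acc_b))
    return out
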