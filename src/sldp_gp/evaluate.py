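"""Prediction accuracy/bias, k-fold cross-validation, and the
(P-value x r^2) grid search that selects SLDP parameters.

Accuracy is the Pearson correlation between GEBV and the evaluation
target (phenotype for real traits, true breeding value for simulated
ones); bias is the ordinary-least-squares slope of the target regressed
on GEBV, with 1 indicating correctly dispersed predictions.  The grid
search crosses the nine-threshold P-value gradient with the twenty-step
r^2 gradient (180 cells by default), runs mark_important -> sldp_prune
-> k-fold CV in every cell, and returns the argmax cell with a
deterministic tie-break (higher accuracy, then smaller panel, then
larger P-threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesr import BayesRConfig, bayesr_fit, bayesr_predict
from .gblup import Grm, build_grm, gblup_predict
from .genotype import GenotypeMatrix, PhenotypeTable
from .gwas import GwasResult, SIGNIFICANCE_GRADIENT
from .ld import MarkerPanel, PruneConfig, mark_important, sldp_prune

__all__ = [
    "GridResult",
    "accuracy",
    "bias",
    "kfold_cv",
    "grid_search",
    "default_p_grid",
    "default_r2_grid",
    "split_populations",
]


def default_p_grid() -> tuple[float, ...]:
    """The nine P-value thresholds (0.0001 to 0.01)."""
    return SIGNIFICANCE_GRADIENT


def default_r2_grid() -> tuple[float, ...]:
    """Twenty r^2 thresholds from 0.05 to 1 in equal steps."""
    return tuple(np.round(np.linspace(0.05, 1.0, 20), 4))


def accuracy(gebv, target) -> float:
    """Pearson correlation between GEBV and the evaluation target."""
    g = np.asarray(getattr(gebv, "gebv", gebv), dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if g.shape != t.shape:
        raise ValueError("GEBV and target must be aligned")
    if g.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(g) == 0 or np.std(t) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(g, t)[0, 1])


def bias(gebv, target) -> float:
    """OLS slope of target on GEBV (1 = unbiased dispersion)."""
    g = np.asarray(getattr(gebv, "gebv", gebv), dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if g.shape != t.shape:
        raise ValueError("GEBV and target must be aligned")
    vg = np.var(g)
    if vg == 0:
        raise ValueError("bias undefined: zero-variance GEBV")
    return float(np.cov(t, g, ddof=0)[0, 1] / vg)


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Random k-way partition with fold sizes differing by at most 1."""
    rng = np.random.default_rng(seed)
    folds = np.tile(np.arange(k), n // k + 1)[:n]
    rng.shuffle(folds)
    return folds


def kfold_cv(gm: GenotypeMatrix, pheno: PhenotypeTable, model: str = "gblup",
             panel: MarkerPanel | None = None, k: int = 5, seed: int = 0,
             target: np.ndarray | None = None,
             bayesr_cfg: BayesRConfig | None = None) -> tuple[float, list[float]]:
    """Mean k-fold cross-validated accuracy (plus the per-fold values).

    Each fold is predicted from the remaining folds; accuracy in a fold
    is the correlation between GEBV and ``target`` (default: phenotype).
    Folds too small for a correlation (e.g. leave-one-out) or with a
    constant phenotype are skipped with a warning; when no fold yields
    one, the accuracy is the pooled correlation over all held-out
    predictions (the leave-one-out convention).
    """
    if k < 2 or len(pheno.samples) < k:
        raise ValueError("need k >= 2 and at least k samples")
    if pheno.samples != list(gm.samples):
        raise ValueError("samples misaligned")
    gm_panel = gm.subset(snps=panel.kept) if panel is not None else gm
    y_target = pheno.y if target is None else np.asarray(target, dtype=np.float64)
    folds = _fold_assignment(len(pheno.samples), k, seed)
    grm = build_grm(gm_panel) if model == "gblup" else None
    fold_acc: list[float] = []
    pooled = np.empty(len(pheno.samples))
    for f in range(k):
        val = np.flatnonzero(folds == f)
        trn = np.flatnonzero(folds != f)
        trn_pheno = PhenotypeTable(
            [pheno.samples[i] for i in trn], pheno.y[trn],
            pheno.covariates.iloc[trn].reset_index(drop=True)
            if len(pheno.covariates) else pd.DataFrame())
        val_ids = [pheno.samples[i] for i in val]
        if model == "gblup":
            pred = gblup_predict(trn_pheno, grm, val_ids)
        elif model == "bayesr":
            cfg = bayesr_cfg or BayesRConfig(seed=seed + 17 * f,
                                             iterations=2000, burnin=500,
                                             thinning=5)
            post = bayesr_fit(gm_panel.subset(samples=trn), trn_pheno, cfg)
            pred = bayesr_predict(post, gm_panel.subset(samples=val))
        else:
            raise ValueError(f"unknown model {model!r}")
        pooled[val] = pred.gebv
        try:
            fold_acc.append(accuracy(pred.gebv, y_target[val]))
        except ValueError as exc:
            import warnings
            warnings.warn(f"fold {f} skipped: {exc}", stacklevel=2)
    if fold_acc:
        return float(np.mean(fold_acc)), fold_acc
    return accuracy(pooled, y_target), fold_acc


@dataclass
class GridResult:
    """Cross-validated accuracy over the (P-threshold, r^2) grid."""

    cells: pd.DataFrame              # columns p, r2, n_snps, accuracy, failed
    best: dict = field(default_factory=dict)
    trait: str = ""
    model: str = "gblup"

    def write(self, path: str) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def grid_search(gm: GenotypeMatrix, pheno: PhenotypeTable, gwas: GwasResult,
                p_grid=None, r2_grid=None, model: str = "gblup", k: int = 5,
                seed: int = 0, cfg_template: PruneConfig | None = None,
                target: np.ndarray | None = None, trait: str = "",
                link_window_bp: int = 1_000_000) -> GridResult:
    """Evaluate every (P-threshold, r^2) cell by SLDP + k-fold CV.

    A cell whose panel comes out empty is recorded as failed and excluded
    from the argmax.  Tie-break for the best cell: highest accuracy, then
    smaller panel, then larger P-threshold.
    """
    p_grid = tuple(p_grid) if p_grid is not None else default_p_grid()
    r2_grid = tuple(r2_grid) if r2_grid is not None else default_r2_grid()
    if not p_grid or not r2_grid:
        raise ValueError("grids must be non-empty")
    window = cfg_template.window_snps if cfg_template else 500
    step = cfg_template.step_snps if cfg_template else 200
    rows = []
    for p_thr in p_grid:
        important = mark_important(gwas, p_thr, gm, link_window_bp=link_window_bp)
        for r2_thr in r2_grid:
            cfg = PruneConfig(r2_threshold=float(r2_thr), window_snps=window,
                              step_snps=step)
            panel = sldp_prune(gm, important, cfg)
            if len(panel) == 0:
                rows.append(dict(p=p_thr, r2=r2_thr, n_snps=0,
                                 accuracy=np.nan, failed=True))
                continue
            acc, _ = kfold_cv(gm, pheno, model=model, panel=panel, k=k,
                              seed=seed, target=target)
            rows.append(dict(p=p_thr, r2=r2_thr, n_snps=len(panel),
                             accuracy=acc, failed=False))
    cells = pd.DataFrame(rows)
    ok = cells[~cells["failed"]]
    if len(ok):
        ranked = ok.sort_values(["accuracy", "n_snps", "p"],
                                ascending=[False, True, False],
                                kind="stable")
        top = ranked.iloc[0]
        best = dict(p=float(top["p"]), r2=float(top["r2"]),
                    n_snps=int(top["n_snps"]), accuracy=float(top["accuracy"]))
    else:
        best = {}
    return GridResult(cells=cells, best=best, trait=trait, model=model)


def split_populations(samples: list[str], n_discovery: int, n_validation: int,
                      seed: int) -> dict[str, list[str]]:
    """Random disjoint discovery / training / validation split.

    Mirrors the three-population scheme in which the GWAS discovery set
    is disjoint from both the CV/training set and the validation set.
    """
    n = len(samples)
    if n_discovery + n_validation >= n:
        raise ValueError("split leaves no training samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    disc = sorted(perm[:n_discovery])
    val = sorted(perm[n_discovery:n_discovery + n_validation])
    trn = sorted(perm[n_discovery + n_validation:])
    return dict(discovery=[samples[i] for i in disc],
                training=[samples[i] for i in trn],
                validation=[samples[i] for i in val])
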