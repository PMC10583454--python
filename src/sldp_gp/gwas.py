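"""Mixed-linear-model association scan and GWAS-derived summaries.

Each SNP is tested as a fixed effect in

    y = X beta + alpha b + g + e,  g ~ N(0, G sigma2_g),  e ~ N(0, I sigma2_e)

with b the 0/1/2 dosage vector and G the genomic relationship matrix.
Variance components are estimated once under the SNP-free null model and
reused for every SNP (the P3D / EMMAX approximation); each SNP then gets
a generalized-least-squares effect estimate and a two-sided 1-df Wald
chi-square test.  Constant (monomorphic) SNPs are flagged untested with
missing statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import Grm, reml_fit, VarianceEstimate
from .genotype import GenotypeMatrix, PhenotypeTable, impute_mean

__all__ = [
    "GwasResult",
    "mlma_scan",
    "select_significant",
    "significance_gradient",
    "qtl_covered_span",
    "false_positive_rate",
    "rank_extremes",
]

#: The nine P-value thresholds of the selection gradient (0.0001 to 0.01).
SIGNIFICANCE_GRADIENT = (1e-4, 3e-4, 5e-4, 7e-4, 1e-3, 3e-3, 5e-3, 7e-3, 1e-2)


@dataclass
class GwasResult:
    """Per-SNP effect, SE, Wald statistic and P-value, variant-aligned."""

    variants: pd.DataFrame
    effect: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    variance: VarianceEstimate | None = None

    def __post_init__(self) -> None:
        m = len(self.variants)
        for name in ("effect", "se", "stat", "p"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have one entry per variant")
            setattr(self, name, arr)
        finite = self.p[np.isfinite(self.p)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("P-values outside [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def tested(self) -> np.ndarray:
        return np.isfinite(self.p)

    def to_frame(self) -> pd.DataFrame:
        df = self.variants[["chrom", "pos", "vid"]].copy()
        df["effect"] = self.effect
        df["se"] = self.se
        df["stat"] = self.stat
        df["p"] = self.p
        return df

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def mlma_scan(gm: GenotypeMatrix, pheno: PhenotypeTable, grm: Grm,
              variance: VarianceEstimate | None = None) -> GwasResult:
    """MLM association scan with P3D variance components.

    ``variance`` may carry pre-computed null-model components (e.g. when
    scanning permuted phenotypes against a fixed genotype panel);
    otherwise they are estimated by REML under the SNP-free null.
    """
    if pheno.samples != list(gm.samples):
        raise ValueError("samples misaligned between genotypes and phenotypes")
    if grm.samples != list(gm.samples):
        raise ValueError("samples misaligned between genotypes and GRM")
    if variance is None:
        variance = reml_fit(pheno, grm, min_samples=10)
    s, u = grm.eig()
    v = variance.sigma2_g * s + variance.sigma2_e
    w = 1.0 / v

    y_t = u.T @ pheno.y
    x_t = u.T @ pheno.design_matrix()
    b = impute_mean(gm.dosage)
    b_t = u.T @ b

    xtw = x_t * w[:, None]
    a_inv = np.linalg.inv(x_t.T @ xtw)
    # P f = W f - W X (X' W X)^-1 X' W f   applied columnwise
    py = w * y_t - xtw @ (a_inv @ (xtw.T @ y_t))
    pb = w[:, None] * b_t - xtw @ (a_inv @ (xtw.T @ b_t))
    b_p_b = np.einsum("ij,ij->j", b_t, pb)
    b_p_y = b_t.T @ py

    sd = np.nanstd(gm.dosage, axis=0)
    testable = (sd > 0) & (b_p_b > 1e-12)
    effect = np.full(gm.n_snps, np.nan)
    se = np.full(gm.n_snps, np.nan)
    stat = np.full(gm.n_snps, np.nan)
    p = np.full(gm.n_snps, np.nan)
    effect[testable] = b_p_y[testable] / b_p_b[testable]
    se[testable] = 1.0 / np.sqrt(b_p_b[testable])
    stat[testable] = b_p_y[testable] ** 2 / b_p_b[testable]
    p[testable] = stats.chi2.sf(stat[testable], df=1)
    return GwasResult(gm.variants.copy(), effect, se, stat, p, variance=variance)


def select_significant(gwas: GwasResult, p_threshold: float) -> np.ndarray:
    """Indices of SNPs with P strictly below the threshold."""
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(gwas.p < p_threshold).astype(np.intp)


def significance_gradient() -> tuple[float, ...]:
    """The nine-threshold P-value gradient used for marker selection."""
    return SIGNIFICANCE_GRADIENT


def qtl_covered_span(variants: pd.DataFrame, flank: int = 50_000
                     ) -> tuple[list[tuple[str, int, int]], int]:
    """QTL-covered regions: ``flank`` bp on either side of each SNP.

    Intervals are half-open [pos - flank, pos + flank), clipped at 0, and
    merged per chromosome when they overlap or touch.  Returns the merged
    interval list and the total covered length in bp.
    """
    if len(variants) == 0:
        return [], 0
    merged: list[tuple[str, int, int]] = []
    for chrom, grp in variants.groupby(variants["chrom"].astype(str), sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        starts = np.clip(pos - flank, 0, None)
        ends = pos + flank
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for st, en in zip(starts[1:], ends[1:]):
            if st <= cur_e:  # overlapping or adjacent
                cur_e = max(cur_e, int(en))
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(st), int(en)
        merged.append((chrom, cur_s, cur_e))
    total = sum(e - s for _, s, e in merged)
    return merged, total


def false_positive_rate(detected: np.ndarray, truth, gm: GenotypeMatrix,
                        r2_cut: float = 0.50) -> float:
    """Fraction of detected SNPs that are neither QTN nor in LD >= r2_cut
    with any QTN (the simulated-trait false-positive rule)."""
    detected = np.asarray(sorted(set(map(int, detected))), dtype=np.intp)
    if detected.size == 0:
        raise ValueError("false-positive rate undefined for an empty detected set")
    qtn = np.asarray(truth.qtn_indices, dtype=np.intp)
    from .ld import _standardized  # shared standardization, r^2 = (z'z / n)^2

    z = _standardized(gm)
    n = gm.n_samples
    informative = np.isin(detected, qtn)
    rest = detected[~informative]
    if rest.size and qtn.size:
        r2 = (z[:, rest].T @ z[:, qtn] / n) ** 2
        linked = (r2 >= r2_cut).any(axis=1)
        informative[~informative] |= linked
    n_false = int((~informative).sum())
    return n_false / detected.size


def rank_extremes(gwas: GwasResult, fraction: float = 0.10
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Top and bottom SNP sets by ascending P (floor(fraction * n) each).

    Untested SNPs (missing P) rank last.  The two sets are disjoint.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    n = gwas.n_snps
    k = int(np.floor(fraction * n))
    p = np.where(np.isfinite(gwas.p), gwas.p, np.inf)
    order = np.argsort(p, kind="stable")
    top = np.sort(order[:k]).astype(np.intp)
    bottom = np.sort(order[n - k:]).astype(np.intp)
    return top, bottom
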