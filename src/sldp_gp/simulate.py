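"""Synthetic diploid genotypes and additive quantitative traits.

The genotype generator draws two haplotypes per individual from a
first-order Markov chain over loci: at each locus the allele is copied
from the previous locus of the same haplotype with probability
``ld_decay``, otherwise drawn fresh at the locus allele frequency.  The
chain restarts at every chromosome boundary, giving block-wise LD that
decays geometrically with marker distance — the property that matters
for LD pruning — with allele frequencies drawn so the minor allele
frequency lies in ``maf_range`` (default [0.05, 0.5], the post-QC
spectrum).

Traits are purely additive: a set of QTN is drawn uniformly without
replacement from the polymorphic loci, QTN effects are sampled from a
standard normal, the true breeding value is the dosage-weighted effect
sum, and the residual variance is set from the realized TBV variance to
hit the requested heritability, Var(e) = Var(TBV) (1 - h^2) / h^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, PhenotypeTable, VARIANT_COLUMNS, compute_maf

__all__ = ["GenoSimConfig", "SimTruth", "simulate_genotypes", "simulate_trait"]


@dataclass(frozen=True)
class GenoSimConfig:
    """Parameters of the Markov-haplotype genotype generator."""

    n_individuals: int
    n_snps: int
    seed: int
    chromosomes: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.9
    bp_spacing: int = 1000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if self.n_individuals < 1 or self.n_snps < 1 or self.chromosomes < 1:
            raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated trait: QTN, effects, TBV, heritability."""

    qtn_indices: np.ndarray
    qtn_effects: np.ndarray
    tbv: np.ndarray
    h2_target: float
    h2_realized: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.qtn_indices = np.asarray(self.qtn_indices, dtype=np.intp)
        self.qtn_effects = np.asarray(self.qtn_effects, dtype=np.float64)
        self.tbv = np.asarray(self.tbv, dtype=np.float64)
        if self.qtn_indices.shape != self.qtn_effects.shape:
            raise ValueError("one effect per QTN required")
        if not 0.0 <= self.h2_realized <= 1.0:
            raise ValueError("realized h2 outside [0, 1]")

    def write(self, path: str, vids: list[str] | None = None) -> None:
        ids = ([vids[i] for i in self.qtn_indices] if vids is not None
               else [f"snp{i}" for i in self.qtn_indices])
        pd.DataFrame({"snp_id": ids, "effect": self.qtn_effects}).to_csv(
            path, sep="\t", index=False
        )


def simulate_genotypes(cfg: GenoSimConfig) -> GenotypeMatrix:
    """Draw a diploid panel with block-wise LD decay (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=m)
    # random allele orientation: frequency of the counted (alt) allele
    p = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)
    bounds = np.linspace(0, m, cfg.chromosomes + 1).astype(int)
    chrom_of = np.zeros(m, dtype=int)
    for c in range(cfg.chromosomes):
        chrom_of[bounds[c]:bounds[c + 1]] = c + 1

    haps = np.empty((2 * n, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(2 * n) < p[j]
        if j == 0 or chrom_of[j] != chrom_of[j - 1]:
            haps[:, j] = fresh
        else:
            copy = rng.random(2 * n) < cfg.ld_decay
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    dosage = (haps[0::2] + haps[1::2]).astype(np.float64)

    pos = np.concatenate([
        (np.arange(bounds[c + 1] - bounds[c]) + 1) * cfg.bp_spacing
        for c in range(cfg.chromosomes)
    ])
    variants = pd.DataFrame(
        dict(chrom=chrom_of.astype(str), pos=pos,
             vid=[f"snp{j}" for j in range(m)], ref="A", alt="G"),
        columns=VARIANT_COLUMNS,
    )
    samples = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(dosage, samples, variants)


def simulate_trait(gm: GenotypeMatrix, n_qtn: int, h2: float, seed: int,
                   maf_min: float = 0.05) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate an additive trait on an existing genotype matrix.

    QTN are drawn uniformly without replacement from SNPs with MAF >=
    ``maf_min`` (the clean panel), effects from N(0, 1); the residual
    variance is Var(TBV) (1 - h2) / h2 so the trait hits the requested
    heritability in expectation.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must be in (0, 1), got {h2}")
    maf = compute_maf(gm)
    with np.errstate(invalid="ignore"):
        eligible = np.flatnonzero(maf >= maf_min)
    if n_qtn > eligible.size:
        raise ValueError(f"requested {n_qtn} QTN but only {eligible.size} "
                         f"SNPs pass MAF >= {maf_min}")
    rng = np.random.default_rng(seed)
    qtn = np.sort(rng.choice(eligible, size=n_qtn, replace=False))
    effects = rng.standard_normal(n_qtn)
    dos = gm.dosage[:, qtn]
    if np.isnan(dos).any():
        from .genotype import impute_mean
        dos = impute_mean(dos)
    tbv = dos @ effects
    var_tbv = float(np.var(tbv))
    if var_tbv == 0.0:
        raise ValueError("degenerate trait: Var(TBV) = 0 (all QTN monomorphic)")
    var_e = var_tbv * (1.0 - h2) / h2
    resid = rng.standard_normal(gm.n_samples) * np.sqrt(var_e)
    y = tbv + resid
    h2_realized = var_tbv / float(np.var(y))
    pheno = PhenotypeTable(list(gm.samples), y)
    truth = SimTruth(qtn, effects, tbv, h2_target=h2,
                     h2_realized=float(np.clip(h2_realized, 0.0, 1.0)), seed=seed)
    return pheno, truth
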