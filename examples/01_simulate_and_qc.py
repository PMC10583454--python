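"""Simulate a diploid SNP panel with block LD and quality-control it.

The generator draws two haplotypes per individual from a first-order
Markov chain (alleles copied from the neighbouring locus with
probability `ld_decay`), giving the block-wise LD structure that LD
pruning operates on.  QC drops low-call-rate individuals first, then
recomputes per-SNP MAF and call rate on the survivors.
"""

import numpy as np

from sldp_gp import GenoSimConfig, compute_maf, qc_filter, simulate_genotypes

gm = simulate_genotypes(GenoSimConfig(n_individuals=500, n_snps=2000,
                                      chromosomes=5, ld_decay=0.9, seed=1))
print(f"simulated panel: {gm.n_samples} individuals x {gm.n_snps} SNPs "
      f"on {gm.variants['chrom'].nunique()} chromosomes")

maf = compute_maf(gm)
print(f"MAF range [{maf.min():.3f}, {maf.max():.3f}] "
      f"(target frequencies have MAF >= 0.05; the haplotype-copying chain "
      f"lets realized frequencies drift slightly, and QC removes strays)")

clean = qc_filter(gm, maf_min=0.05, snp_call_min=0.95, ind_call_min=0.90)
print(f"after QC (MAF >= 0.05, SNP call >= 0.95, ind call >= 0.90): "
      f"{clean.n_samples} individuals, {clean.n_snps} SNPs retained")

# adjacent-marker LD, the quantity pruning thresholds act on
d = clean.dosage
r2 = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
      for j in range(0, 200)
      if d[:, j].std() > 0 and d[:, j + 1].std() > 0]
print(f"mean adjacent-pair r^2 = {np.mean(r2):.3f} "
      f"(high values mean redundant markers that pruning removes)")
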