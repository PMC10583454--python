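import numpy as np
import pandas as pd
import pytest

from sldp_gp.genotype import GenotypeMatrix, PhenotypeTable, VARIANT_COLUMNS
from sldp_gp.simulate import GenoSimConfig, simulate_genotypes, simulate_trait


def make_gm(dosage, chrom=None, pos=None, spacing=1000) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array for unit tests."""
    dosage = np.asarray(dosage, dtype=np.float64)
    n, m = dosage.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else [(j + 1) * spacing for j in range(m)]
    variants = pd.DataFrame(
        dict(chrom=[str(c) for c in chrom], pos=list(pos),
             vid=[f"s{j}" for j in range(m)], ref="A", alt="G"),
        columns=VARIANT_COLUMNS,
    )
    return GenotypeMatrix(dosage, [f"i{i}" for i in range(n)], variants)


def make_pheno(gm: GenotypeMatrix, y, **covs) -> PhenotypeTable:
    cov = pd.DataFrame(covs) if covs else pd.DataFrame()
    return PhenotypeTable(list(gm.samples), np.asarray(y, dtype=float), cov)


@pytest.fixture(scope="session")
def small_panel():
    """300 individuals x 600 SNPs on two chromosomes with block LD."""
    return simulate_genotypes(
        GenoSimConfig(n_individuals=300, n_snps=600, seed=11, chromosomes=2,
                      ld_decay=0.9)
    )


@pytest.fixture(scope="session")
def small_trait(small_panel):
    """A 100-QTN h2=0.5 trait on the small panel (phenotypes + truth).

    100 QTN mirrors the major-gene simulation scenario and keeps per-QTN
    variance shares within the BayesR mixture's design range.
    """
    return simulate_trait(small_panel, n_qtn=100, h2=0.5, seed=13)
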