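"""Genotype containers, file I/O, quality control and panel extraction.

Genotypes are held as an additive-dosage matrix (individuals x SNPs,
counting copies of the alternate allele: 0, 1 or 2) with per-variant
metadata.  Missing calls are stored as NaN.  Downstream modules that need
a complete matrix (GRM construction, LD) mean-impute missing entries per
SNP; that convention is defined once here (:func:`impute_mean`) and reused.

Supported on-disk formats: VCF 4.x (diploid GT field, biallelic records),
PLINK text (.ped/.map) and a headered TSV dosage table (rows = samples,
columns = SNP ids).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "PhenotypeTable",
    "GenotypeParseError",
    "EmptyResultError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "compute_maf",
    "qc_filter",
    "extract_panel",
    "impute_mean",
]

VARIANT_COLUMNS = ["chrom", "pos", "vid", "ref", "alt"]


class GenotypeParseError(ValueError):
    """A genotype file violated its format contract."""


class EmptyResultError(ValueError):
    """An operation removed every SNP or every individual."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP locus (1-based coordinate, VCF convention)."""

    chrom: str
    pos: int
    vid: str
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with variant metadata.

    Parameters
    ----------
    dosage
        Float array of shape (n_samples, n_snps); entries in {0, 1, 2}
        or NaN for uncalled genotypes.
    samples
        Sample identifiers, one per row.
    variants
        DataFrame with columns chrom, pos, vid, ref, alt, one row per
        column of ``dosage``, sorted by (chrom, pos).
    """

    dosage: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        self.samples = list(self.samples)
        self.variants = self.variants.reset_index(drop=True)
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} dosage rows")
        if m != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but {m} dosage columns")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage entries must be 0/1/2 or NaN, found {bad}")
        if self.variants["vid"].duplicated().any():
            dup = self.variants.loc[self.variants["vid"].duplicated(), "vid"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def variant(self, j: int) -> Variant:
        row = self.variants.iloc[j]
        return Variant(str(row.chrom), int(row.pos), str(row.vid), str(row.ref), str(row.alt))

    def subset(self, samples: np.ndarray | list | None = None,
               snps: np.ndarray | list | None = None) -> "GenotypeMatrix":
        """Row/column subset by positional index (order preserved)."""
        d = self.dosage
        smp = self.samples
        var = self.variants
        if samples is not None:
            samples = np.asarray(samples)
            d = d[samples, :]
            smp = [self.samples[i] for i in samples]
        if snps is not None:
            snps = np.asarray(snps)
            d = d[:, snps]
            var = var.iloc[snps]
        return GenotypeMatrix(d.copy(), smp, var.reset_index(drop=True))

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)


@dataclass
class PhenotypeTable:
    """Per-sample trait values with optional categorical fixed effects."""

    samples: list[str]
    y: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.y = np.asarray(self.y, dtype=np.float64)
        if len(self.samples) != len(self.y):
            raise ValueError("one trait value required per sample")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in phenotype table")
        if len(self.covariates) not in (0, len(self.samples)):
            raise ValueError("covariate rows must match samples")
        for col in self.covariates.columns:
            if self.covariates[col].astype(str).str.len().eq(0).any():
                raise ValueError(f"empty level in covariate {col!r}")

    def design_matrix(self) -> np.ndarray:
        """Intercept plus full-rank indicator contrasts for each covariate."""
        n = len(self.samples)
        cols = [np.ones(n)]
        for name in self.covariates.columns:
            levels = pd.Categorical(self.covariates[name].astype(str))
            dummies = pd.get_dummies(levels, drop_first=True).to_numpy(dtype=np.float64)
            cols.append(dummies)
        return np.column_stack(cols) if len(cols) > 1 else cols[0][:, None]

    def reindex(self, ids: list[str]) -> "PhenotypeTable":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples without phenotypes: {missing[:5]}")
        idx = [lookup[s] for s in ids]
        cov = self.covariates.iloc[idx].reset_index(drop=True) if len(self.covariates) else pd.DataFrame()
        return PhenotypeTable(list(ids), self.y[idx], cov)


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(path: str | os.PathLike, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF, PLINK text, or a dosage TSV.

    ``format`` is one of ``vcf``, ``plink-text``, ``dosage-table``; when
    omitted it is inferred from the file extension (.vcf, .ped, .tsv/.txt).
    """
    path = os.fspath(path)
    if format is None:
        if path.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif path.endswith(".ped"):
            format = "plink-text"
        else:
            format = "dosage-table"
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink-text":
        return _read_plink_text(path)
    if format == "dosage-table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise GenotypeParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    lineno = len(vcf.raw_header.splitlines())
    try:
        for rec in vcf:
            lineno += 1
            if len(rec.ALT) != 1:
                raise GenotypeParseError(
                    f"{path} line {lineno}: multi-allelic record at "
                    f"{rec.CHROM}:{rec.POS}; only biallelic SNPs are supported"
                )
            gts = rec.genotype.array()  # (n, ploidy+1); last col = phased flag
            if gts.shape[1] - 1 != 2:
                raise GenotypeParseError(
                    f"{path} line {lineno}: non-diploid GT at {rec.CHROM}:{rec.POS}"
                )
            alleles = gts[:, :2].astype(np.float64)
            dos = alleles.sum(axis=1)
            dos[(alleles < 0).any(axis=1)] = np.nan  # uncalled -> missing
            cols.append(dos)
            rows.append(
                dict(chrom=rec.CHROM, pos=rec.POS, vid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                     ref=rec.REF, alt=rec.ALT[0])
            )
    except GenotypeParseError:
        raise
    except Exception as exc:
        raise GenotypeParseError(f"{path} line {lineno + 1}: malformed record ({exc})") from exc
    if not rows:
        raise GenotypeParseError(f"{path}: no variant records")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.column_stack(cols)
    return _sorted_matrix(dosage, samples, variants)


def _read_plink_text(ped_path: str) -> GenotypeMatrix:
    map_path = ped_path[:-4] + ".map" if ped_path.endswith(".ped") else ped_path + ".map"
    if not os.path.exists(map_path):
        raise GenotypeParseError(f"missing companion .map file for {ped_path}")
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path} line {lineno}: expected 4 columns")
            rows.append(dict(chrom=parts[0], pos=int(parts[3]), vid=parts[1], ref="A", alt="B"))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    m = len(variants)
    samples, geno_rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            alleles = parts[6:]
            dos = np.full(m, np.nan)
            for j in range(m):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    continue
                dos[j] = (a != "A") + (b != "A")  # counts of non-reference allele
            geno_rows.append(dos)
    if not samples:
        raise GenotypeParseError(f"{ped_path}: no samples")
    return _sorted_matrix(np.array(geno_rows), samples, variants)


def _read_dosage_table(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise GenotypeParseError(f"cannot parse dosage table {path}: {exc}") from exc
    meta_path = path + ".vars"
    if os.path.exists(meta_path):
        variants = pd.read_csv(meta_path, sep="\t")[VARIANT_COLUMNS]
    else:
        # fall back to synthesising coordinates from column order
        variants = pd.DataFrame(
            dict(chrom="1", pos=np.arange(1, df.shape[1] + 1), vid=list(df.columns),
                 ref="A", alt="G"), columns=VARIANT_COLUMNS
        )
    return _sorted_matrix(df.to_numpy(dtype=np.float64), [str(s) for s in df.index], variants)


def _sorted_matrix(dosage: np.ndarray, samples: list[str], variants: pd.DataFrame) -> GenotypeMatrix:
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].astype(str).to_numpy()))
    return GenotypeMatrix(dosage[:, order], samples, variants.iloc[order])


def write_genotypes(gm: GenotypeMatrix, path: str | os.PathLike, format: str = "vcf") -> None:
    """Write a genotype matrix as VCF or a dosage TSV (plus .vars metadata)."""
    path = os.fspath(path)
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "dosage-table":
        pd.DataFrame(gm.dosage, index=gm.samples, columns=gm.variants["vid"]).to_csv(
            path, sep="\t", index_label="sample"
        )
        gm.variants.to_csv(path + ".vars", sep="\t", index=False)
    else:
        raise ValueError(f"unsupported output format {format!r}")


def _write_vcf(gm: GenotypeMatrix, path: str) -> None:
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, row in gm.variants.iterrows():
            calls = "\t".join(
                gt_code.get(gm.dosage[i, j], "./.") for i in range(gm.n_samples)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.vid}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{calls}\n")


def read_phenotypes(path: str | os.PathLike, covariates: list[str] | None = None) -> PhenotypeTable:
    """Read a phenotype TSV: columns id, y, then optional covariates."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    ids = df.iloc[:, 0].astype(str).tolist()
    y = df.iloc[:, 1].to_numpy(dtype=np.float64)
    cov_cols = covariates if covariates is not None else list(df.columns[2:])
    cov = df[cov_cols].reset_index(drop=True) if cov_cols else pd.DataFrame()
    return PhenotypeTable(ids, y, cov)


# ---------------------------------------------------------------------------
# QC and derived statistics


def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency; NaN for SNPs with no called genotype.

    freq = min(p, 1-p) with p the alternate-allele frequency over called
    genotypes (alt count / 2 x calls).
    """
    with np.errstate(invalid="ignore"):
        called = np.sum(~np.isnan(gm.dosage), axis=0)
        alt = np.nansum(gm.dosage, axis=0)
        p = np.where(called > 0, alt / (2.0 * np.maximum(called, 1)), np.nan)
    return np.minimum(p, 1.0 - p)


def qc_filter(gm: GenotypeMatrix, maf_min: float = 0.05, snp_call_min: float = 0.95,
              ind_call_min: float = 0.90) -> GenotypeMatrix:
    """Quality-control filter: individual call rate, then SNP MAF/call rate.

    Individuals with call rate below ``ind_call_min`` are dropped first;
    SNP statistics are then recomputed on the survivors, and SNPs with
    MAF < ``maf_min`` or call rate < ``snp_call_min`` are removed.
    """
    for name, v in (("maf_min", maf_min), ("snp_call_min", snp_call_min),
                    ("ind_call_min", ind_call_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    called = ~np.isnan(gm.dosage)
    ind_rate = called.mean(axis=1)
    keep_ind = np.flatnonzero(ind_rate >= ind_call_min)
    if keep_ind.size == 0:
        raise EmptyResultError("QC removed every individual")
    gm2 = gm.subset(samples=keep_ind) if keep_ind.size < gm.n_samples else gm
    snp_rate = (~np.isnan(gm2.dosage)).mean(axis=0)
    maf = compute_maf(gm2)
    with np.errstate(invalid="ignore"):
        keep_snp = np.flatnonzero((snp_rate >= snp_call_min) & (maf >= maf_min))
    if keep_snp.size == 0:
        raise EmptyResultError("QC removed every SNP")
    if keep_snp.size == gm2.n_snps and gm2 is gm:
        return gm
    return gm2.subset(snps=keep_snp)


def extract_panel(gm: GenotypeMatrix, targets: list[tuple[str, int]],
                  max_dist: int = 1000) -> GenotypeMatrix:
    """Emulate a lower-density panel (SNP chip / GBS) from a dense matrix.

    For each target (chrom, pos): take the SNP at that exact position if
    present, otherwise the nearest SNP within ``max_dist`` bp (ties broken
    toward the lower position), otherwise drop the target.  Each source
    SNP is used at most once.
    """
    chroms = gm.variants["chrom"].astype(str).to_numpy()
    pos = gm.variants["pos"].to_numpy()
    taken: set[int] = set()
    chosen: list[int] = []
    by_chrom: dict[str, np.ndarray] = {
        c: np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms)
    }
    for chrom, tpos in targets:
        idx = by_chrom.get(str(chrom))
        if idx is None or idx.size == 0:
            continue
        cpos = pos[idx]
        lo = np.searchsorted(cpos, tpos - max_dist, side="left")
        hi = np.searchsorted(cpos, tpos + max_dist, side="right")
        cands = [(abs(int(cpos[c]) - int(tpos)), int(cpos[c]), int(idx[c]))
                 for c in range(lo, hi)]
        # nearest wins; ties broken toward the lower position
        for _, _, j in sorted(cands):
            if j not in taken:
                taken.add(j)
                chosen.append(j)
                break
    return gm.subset(snps=np.array(sorted(chosen), dtype=np.intp))


def impute_mean(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per SNP (the package-wide convention)."""
    if not np.isnan(dosage).any():
        return dosage
    out = dosage.copy()
    col_mean = np.nanmean(out, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out
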