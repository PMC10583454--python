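"""Pairwise linkage disequilibrium and sliding-window pruning.

Two pruning variants are provided:

* **LDP** (:func:`ld_prune`) — classical sliding-window pruning: within a
  window of ``window_snps`` markers, any pair with r^2 at or above the
  threshold loses one member; the window then advances by ``step_snps``
  over the surviving markers of the chromosome.
* **SLDP** (:func:`sldp_prune`) — the same scan, except that a designated
  set of "important SNPs" (GWAS-significant markers or markers in high LD
  with them, see :func:`mark_important`) is never removed; a violating
  pair made of one important and one ordinary SNP drops the ordinary one,
  and an important/important pair drops neither.

r^2 is the squared Pearson correlation of mean-imputed dosage vectors
(composite LD, the convention of standard pruning tools).  Within a
window, pairs are scanned by increasing index and a violating pair drops
the member with the lower minor allele frequency (ties drop the higher
index); removals take effect immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotype import GenotypeMatrix, compute_maf, impute_mean

__all__ = [
    "PruneConfig",
    "MarkerPanel",
    "pairwise_r2",
    "ld_prune",
    "sldp_prune",
    "mark_important",
]


@dataclass(frozen=True)
class PruneConfig:
    """Sliding-window pruning parameters (window/step in SNP counts)."""

    r2_threshold: float
    window_snps: int = 500
    step_snps: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError(f"r2_threshold must be in (0, 1], got {self.r2_threshold}")
        if not 0 < self.step_snps <= self.window_snps:
            raise ValueError("need 0 < step_snps <= window_snps")


@dataclass
class MarkerPanel:
    """An ordered subset of a genotype matrix's SNP columns."""

    kept: np.ndarray
    provenance: str = "panel"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kept = np.asarray(self.kept, dtype=np.intp)
        if self.kept.size and np.any(np.diff(self.kept) <= 0):
            raise ValueError("kept indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.kept.size)

    def write(self, path: str) -> None:
        """One SNP id per line (PLINK --extract dialect); requires ids."""
        ids = self.parameters.get("vids")
        if ids is None:
            raise ValueError("panel has no SNP ids attached")
        with open(path, "w") as fh:
            for v in ids:
                fh.write(f"{v}\n")


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are mean-imputed per vector.  A constant vector has
    undefined LD; callers treat that as r^2 = 0, so 0.0 is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must share a length of at least 2")
    x = impute_mean(x[:, None])[:, 0]
    y = impute_mean(y[:, None])[:, 0]
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0.0 or vy == 0.0:
        return 0.0
    r = (xc @ yc) / np.sqrt(vx * vy)
    return float(min(r * r, 1.0))


#: Absolute slack on the removal comparison so that r^2 = 1 computed in
#: floating point (e.g. 1 - 1e-15 for a duplicated column) is still removed
#: at threshold 1.
R2_EPS = 1e-9


@njit(cache=True)
def _prune_window(r2: np.ndarray, maf: np.ndarray, important: np.ndarray,
                  alive: np.ndarray, thr: float) -> None:
    """Greedy in-place scan of one window (pairs by increasing index)."""
    w = r2.shape[0]
    thr = thr - R2_EPS
    for i in range(w):
        if not alive[i]:
            continue
        for j in range(i + 1, w):
            if not alive[i]:
                break
            if not alive[j]:
                continue
            if r2[i, j] >= thr:
                if important[i] and important[j]:
                    continue
                if important[i]:
                    alive[j] = False
                elif important[j]:
                    alive[i] = False
                elif maf[i] < maf[j]:
                    alive[i] = False
                else:
                    # lower MAF loses; ties drop the higher index
                    alive[j] = False


def _standardized(gm: GenotypeMatrix) -> np.ndarray:
    x = impute_mean(gm.dosage)
    xc = x - x.mean(axis=0)
    sd = np.sqrt((xc ** 2).mean(axis=0))
    sd[sd == 0.0] = np.inf  # constant SNP -> r^2 0 against everything
    return xc / sd


def _windowed_prune(gm: GenotypeMatrix, cfg: PruneConfig,
                    important_mask: np.ndarray) -> np.ndarray:
    """Run the windowed scan per chromosome; return global kept indices."""
    n = gm.n_samples
    z = _standardized(gm)
    maf = compute_maf(gm)
    maf = np.where(np.isnan(maf), 0.0, maf)
    chroms = gm.variants["chrom"].astype(str).to_numpy()
    kept_global: list[np.ndarray] = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        alive_idx = list(idx)
        offset = 0
        while True:
            window = alive_idx[offset:offset + cfg.window_snps]
            if len(window) > 1:
                widx = np.asarray(window, dtype=np.intp)
                zw = z[:, widx]
                r2 = (zw.T @ zw / n) ** 2
                alive = np.ones(len(window), dtype=np.bool_)
                _prune_window(r2, maf[widx], important_mask[widx], alive,
                              cfg.r2_threshold)
                removed = {window[k] for k in range(len(window)) if not alive[k]}
                if removed:
                    alive_idx = [i for i in alive_idx if i not in removed]
            if offset + cfg.window_snps >= len(alive_idx):
                break
            offset += cfg.step_snps
        kept_global.append(np.asarray(alive_idx, dtype=np.intp))
    return np.sort(np.concatenate(kept_global)) if kept_global else np.array([], dtype=np.intp)


def ld_prune(gm: GenotypeMatrix, cfg: PruneConfig) -> MarkerPanel:
    """Sliding-window LD pruning over each chromosome."""
    mask = np.zeros(gm.n_snps, dtype=np.bool_)
    kept = _windowed_prune(gm, cfg, mask)
    return MarkerPanel(kept, provenance="LDP",
                       parameters=dict(r2_threshold=cfg.r2_threshold,
                                       window_snps=cfg.window_snps,
                                       step_snps=cfg.step_snps,
                                       vids=gm.variants["vid"].to_numpy()[kept].tolist()))


def sldp_prune(gm: GenotypeMatrix, important: np.ndarray | set,
               cfg: PruneConfig) -> MarkerPanel:
    """Selective LD pruning: like :func:`ld_prune` but the ``important``
    index set is always retained."""
    important = np.asarray(sorted(set(map(int, important))), dtype=np.intp)
    if important.size and (important.min() < 0 or important.max() >= gm.n_snps):
        raise IndexError("important indices out of range")
    mask = np.zeros(gm.n_snps, dtype=np.bool_)
    mask[important] = True
    kept = _windowed_prune(gm, cfg, mask)
    return MarkerPanel(kept, provenance="SLDP",
                       parameters=dict(r2_threshold=cfg.r2_threshold,
                                       window_snps=cfg.window_snps,
                                       step_snps=cfg.step_snps,
                                       n_important=int(important.size),
                                       vids=gm.variants["vid"].to_numpy()[kept].tolist()))


def mark_important(gwas, p_threshold: float, gm: GenotypeMatrix,
                   r2_link: float = 0.90, link_window_bp: int = 1_000_000) -> np.ndarray:
    """Important-SNP set for SLDP: GWAS hits plus their high-LD partners.

    Returns sorted indices of SNPs with P < ``p_threshold`` together with
    SNPs whose r^2 with any such hit exceeds ``r2_link`` within
    ``link_window_bp`` of it.
    """
    p = np.asarray(gwas.p if hasattr(gwas, "p") else gwas, dtype=np.float64)
    if p.shape[0] != gm.n_snps:
        raise ValueError("GWAS result not aligned to genotype matrix")
    with np.errstate(invalid="ignore"):
        sig = np.flatnonzero(p < p_threshold)
    if sig.size == 0:
        return np.array([], dtype=np.intp)
    n = gm.n_samples
    z = _standardized(gm)
    chroms = gm.variants["chrom"].astype(str).to_numpy()
    pos = gm.variants["pos"].to_numpy()
    linked = np.zeros(gm.n_snps, dtype=bool)
    linked[sig] = True
    for s in sig:
        same = np.flatnonzero(chroms == chroms[s])
        near = same[np.abs(pos[same] - pos[s]) <= link_window_bp]
        cand = near[~linked[near]]
        if cand.size == 0:
            continue
        r2 = (z[:, cand].T @ z[:, s] / n) ** 2
        linked[cand[r2 > r2_link]] = True
    return np.flatnonzero(linked).astype(np.intp)
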