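"""Genomic relationship matrix, REML variance components, GBLUP.

The model is the standard animal-model mixed model

    y = X beta + u + e,   u ~ N(0, G sigma2_g),   e ~ N(0, I sigma2_e)

with G the genomic relationship matrix from per-SNP standardized dosages
(z_j = (x_j - 2 p_j) / sqrt(2 p_j (1 - p_j)), G = Z Z' / m).  Variance
components are estimated by restricted maximum likelihood.  Because the
model has a single genetic variance, the restricted likelihood can be
profiled down to one dimension in the variance ratio delta = sigma2_e /
sigma2_g on the eigenbasis of G; the fit is an exact one-dimensional
search (coarse grid plus Brent refinement) on that profile, which is
globally convergent and reuses one eigendecomposition for the REML fit,
the association scan and prediction.  Standard errors come from the
Fisher information of (sigma2_g, sigma2_e) at the optimum; the h^2
standard error is delta-method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .genotype import GenotypeMatrix, PhenotypeTable, compute_maf, impute_mean

__all__ = [
    "Grm",
    "VarianceEstimate",
    "PredictionResult",
    "RemlError",
    "build_grm",
    "reml_fit",
    "gblup_predict",
    "snp_blup_effects",
]

_DELTA_LOG_BOUNDS = (-14.0, 14.0)


class RemlError(RuntimeError):
    """REML failed (non-finite likelihood or singular system)."""


@dataclass
class Grm:
    """Genomic relationship matrix over a named sample list."""

    matrix: np.ndarray
    samples: list[str]
    snp_count: int
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.samples)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square over the sample list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.samples)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues clipped at 0)."""
        if self._eig is None:
            s, u = np.linalg.eigh(self.matrix)
            self._eig = (np.clip(s, 0.0, None), u)
        return self._eig

    def submatrix(self, idx: np.ndarray) -> "Grm":
        idx = np.asarray(idx, dtype=np.intp)
        return Grm(self.matrix[np.ix_(idx, idx)],
                   [self.samples[i] for i in idx], self.snp_count)

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in GRM: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)


@dataclass
class VarianceEstimate:
    """REML additive and residual variances with standard errors."""

    sigma2_g: float
    sigma2_e: float
    se_sigma2_g: float
    se_sigma2_e: float
    se_h2: float
    boundary: bool
    converged: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else 0.0


@dataclass
class PredictionResult:
    """Per-sample genomic estimated breeding values."""

    samples: list[str]
    gebv: np.ndarray
    model: str = "gblup"
    panel: str = ""

    def __post_init__(self) -> None:
        self.gebv = np.asarray(self.gebv, dtype=np.float64)
        if len(self.samples) != len(self.gebv):
            raise ValueError("one GEBV required per sample")
        if not np.isfinite(self.gebv).all():
            raise ValueError("non-finite GEBV")


def standardize_dosage(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP standardized dosage Z and the polymorphic-SNP mask."""
    maf = compute_maf(gm)
    with np.errstate(invalid="ignore"):
        poly = (maf > 0) & ~np.isnan(maf)
    x = impute_mean(gm.dosage[:, poly])
    p = np.nansum(gm.dosage[:, poly], axis=0) / (
        2.0 * np.sum(~np.isnan(gm.dosage[:, poly]), axis=0)
    )
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return z, poly


def build_grm(gm: GenotypeMatrix) -> Grm:
    """Yang-style GRM: G = Z Z' / m over polymorphic SNPs."""
    z, poly = standardize_dosage(gm)
    m = int(poly.sum())
    if m < 2:
        raise ValueError(f"need >= 2 polymorphic SNPs to build a GRM, have {m}")
    g = z @ z.T / m
    return Grm(g, list(gm.samples), m)


# ---------------------------------------------------------------------------
# REML on the eigenbasis of G


def _profile_reml(delta_log: float, s: np.ndarray, yt: np.ndarray,
                  xt: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Restricted log-likelihood profiled over sigma2_g at fixed delta.

    Returns (-2 * restricted LL up to a constant, sigma2_g_hat, beta_hat).
    """
    delta = np.exp(delta_log)
    n, p = xt.shape
    w = 1.0 / (s + delta)
    xtw = xt * w[:, None]
    a = xt.T @ xtw
    try:
        beta = np.linalg.solve(a, xtw.T @ yt)
    except np.linalg.LinAlgError as exc:
        raise RemlError("singular fixed-effect system in REML") from exc
    r = yt - xt @ beta
    rss = float(r @ (w * r))
    df = n - p
    sg = rss / df
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0 or sg <= 0:
        return np.inf, sg, beta
    neg2ll = df * np.log(sg) + float(np.sum(np.log(s + delta))) + logdet_a
    return neg2ll, sg, beta


def reml_fit(pheno: PhenotypeTable, grm: Grm, min_samples: int = 30) -> VarianceEstimate:
    """REML estimates of (sigma2_g, sigma2_e) for y = X beta + u + e."""
    if len(pheno.samples) < min_samples:
        raise ValueError(f"REML needs >= {min_samples} samples, have {len(pheno.samples)}")
    if pheno.samples != grm.samples:
        pheno = pheno.reindex(grm.samples)
    s, u = grm.eig()
    y = pheno.y
    x = pheno.design_matrix()
    yt = u.T @ y
    xt = u.T @ x

    grid = np.linspace(*_DELTA_LOG_BOUNDS, 41)
    vals = np.array([_profile_reml(t, s, yt, xt)[0] for t in grid])
    if not np.isfinite(vals).any():
        raise RemlError("restricted likelihood non-finite over the whole grid; "
                        f"trace: {list(zip(grid, vals))[:5]}")
    k = int(np.nanargmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(lambda t: _profile_reml(t, s, yt, xt)[0],
                          bounds=(lo, hi), method="bounded",
                          options=dict(xatol=1e-10))
    t_star = float(res.x) if res.fun <= vals[k] else float(grid[k])
    neg2ll, sg, _ = _profile_reml(t_star, s, yt, xt)
    delta = np.exp(t_star)
    sigma2_g = sg
    sigma2_e = delta * sg
    boundary = t_star >= _DELTA_LOG_BOUNDS[1] - 0.5 or t_star <= _DELTA_LOG_BOUNDS[0] + 0.5

    # Fisher information of (sigma2_g, sigma2_e) via the REML projection P
    v = sigma2_g * s + sigma2_e
    w = 1.0 / v
    xtw = xt * w[:, None]
    a_inv = np.linalg.inv(xt.T @ xtw)
    p_mat = np.diag(w) - xtw @ a_inv @ xtw.T
    pg = p_mat * s[None, :]
    i_gg = 0.5 * float(np.sum(pg * pg.T))
    i_ge = 0.5 * float(np.sum(pg * p_mat))
    i_ee = 0.5 * float(np.sum(p_mat * p_mat))
    info = np.array([[i_gg, i_ge], [i_ge, i_ee]])
    try:
        cov = np.linalg.inv(info)
        se_g, se_e = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        tot = sigma2_g + sigma2_e
        grad = np.array([sigma2_e, -sigma2_g]) / tot ** 2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_g = se_e = se_h2 = float("nan")

    return VarianceEstimate(
        sigma2_g=float(sigma2_g), sigma2_e=float(sigma2_e),
        se_sigma2_g=float(se_g), se_sigma2_e=float(se_e), se_h2=se_h2,
        boundary=bool(boundary),
        converged=dict(method="profiled-REML", neg2ll=float(neg2ll),
                       delta=float(delta), grid_evals=len(grid),
                       brent_evals=int(res.nfev)),
    )


def gblup_predict(pheno_train: PhenotypeTable, grm_all: Grm,
                  predict_ids: list[str],
                  variance: VarianceEstimate | None = None,
                  model_label: str = "gblup", panel_label: str = "") -> PredictionResult:
    """GEBV for ``predict_ids`` from the mixed-model equations at the REML
    estimates; validation individuals contribute no phenotype."""
    if len(set(pheno_train.samples)) != len(pheno_train.samples):
        raise ValueError("singular system: duplicate training samples")
    train_idx = grm_all.sample_index(pheno_train.samples)
    pred_idx = grm_all.sample_index(list(predict_ids))
    g_tt = grm_all.submatrix(train_idx)
    if variance is None:
        variance = reml_fit(pheno_train, g_tt)
    sg, se = variance.sigma2_g, variance.sigma2_e
    if sg + se <= 0:
        raise RemlError("singular covariance: sigma2_g + sigma2_e = 0")
    v = sg * g_tt.matrix + se * np.eye(g_tt.n)
    x = pheno_train.design_matrix()
    y = pheno_train.y
    try:
        vi_x = np.linalg.solve(v, x)
        beta = np.linalg.solve(x.T @ vi_x, vi_x.T @ y)
        alpha = np.linalg.solve(v, y - x @ beta)
    except np.linalg.LinAlgError as exc:
        raise RemlError("singular coefficient matrix (duplicate samples or "
                        "zero residual variance)") from exc
    gebv = sg * (grm_all.matrix[np.ix_(pred_idx, train_idx)] @ alpha)
    return PredictionResult(list(predict_ids), gebv, model=model_label, panel=panel_label)


def snp_blup_effects(z_train: np.ndarray, pheno_train: PhenotypeTable,
                     sigma2_g: float, sigma2_e: float) -> np.ndarray:
    """Ridge (SNP-BLUP) effects for standardized dosages Z with
    lambda = m sigma2_e / sigma2_g; the GBLUP dual with G = Z Z' / m."""
    n, m = z_train.shape
    x = pheno_train.design_matrix()
    y = pheno_train.y
    v = (sigma2_g / m) * (z_train @ z_train.T) + sigma2_e * np.eye(n)
    vi_x = np.linalg.solve(v, x)
    beta = np.linalg.solve(x.T @ vi_x, vi_x.T @ y)
    resid = np.linalg.solve(v, y - x @ beta)
    return (sigma2_g / m) * (z_train.T @ resid)
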