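"""LD pruning and principal component analysis of genotype dosages.

Pruning is the classic greedy windowed r^2 filter; PCA standardizes
dosages by the estimated allele frequency (centering by 2p, scaling by
sqrt(2p(1-p))) so that component variance fractions carry the usual
population-structure interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import GenotypeMatrix

__all__ = ["PruneConfig", "PcaResult", "ld_prune", "pca"]

log = logging.getLogger(__name__)


@dataclass
class PruneConfig:
    window: int = 50  # window size in variants
    step: int = 5
    r2: float = 0.5

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError("require window >= step >= 1")
        if not (0 < self.r2 <= 1):
            raise ValueError("r2 threshold must be in (0, 1]")


def _imputed_dosage(g: GenotypeMatrix) -> np.ndarray:
    """(samples, variants) dosage with per-variant mean imputation."""
    d = g.dosage()
    mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    mean = np.nan_to_num(mean)  # all-missing variant -> 0
    miss = np.isnan(d)
    d[miss] = np.broadcast_to(mean, d.shape)[miss]
    return d


def ld_prune(g: GenotypeMatrix, cfg: PruneConfig | None = None) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained variant indices.

    Within each sliding window, while any retained pair has squared
    Pearson dosage correlation above the threshold, the pair with the
    highest r^2 is found and the member with the lower call rate (ties:
    the later position) is dropped. Deterministic.
    """
    cfg = cfg or PruneConfig()
    m = g.n_variants
    if m == 0:
        return np.array([], dtype=np.intp)
    dose = _imputed_dosage(g)
    call_rate = g.call_rate()
    removed = np.zeros(m, dtype=bool)
    sd = dose.std(axis=0)

    for start in range(0, m, cfg.step):
        idx = [
            i
            for i in range(start, min(start + cfg.window, m))
            if not removed[i] and sd[i] > 0
        ]
        while len(idx) > 1:
            block = dose[:, idx]
            r = np.corrcoef(block, rowvar=False)
            r2 = r**2
            np.fill_diagonal(r2, 0.0)
            if np.nanmax(r2) <= cfg.r2:
                break
            flat = np.nanargmax(r2)
            i, j = divmod(flat, len(idx))
            vi, vj = idx[i], idx[j]
            # drop the lower call-rate member; ties -> later position
            if call_rate[vi] < call_rate[vj]:
                drop = vi
            elif call_rate[vj] < call_rate[vi]:
                drop = vj
            else:
                drop = max(vi, vj)
            removed[drop] = True
            idx.remove(drop)
        if start + cfg.window >= m:
            break
    retained = np.flatnonzero(~removed)
    log.info("ld_prune: retained %d of %d variants", retained.size, m)
    return retained


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending, length k
    scores: np.ndarray  # (n_samples, k)
    variance_fraction: np.ndarray  # eigenvalue / trace of covariance
    loadings: np.ndarray  # (n_variants_used, k)
    samples: list[str]
    used_variants: np.ndarray  # indices into the input matrix
    excluded_zero_variance: np.ndarray


def pca(
    g: GenotypeMatrix,
    retained: np.ndarray | None = None,
    k: int = 10,
) -> PcaResult:
    """PCA of frequency-standardized dosages.

    Missing dosages are mean-imputed per variant; each variant column is
    centered by ``2 p_hat`` and scaled by ``sqrt(2 p_hat (1 - p_hat))``.
    Eigenpairs come from the SVD of the standardized matrix; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    if retained is None:
        retained = np.arange(g.n_variants)
    retained = np.asarray(retained, dtype=np.intp)
    sub = g.subset(variant_idx=retained)
    k = min(k, sub.n_samples - 1, sub.n_variants)
    if k < 1:
        raise ValueError("k must be >= 1 after bounding by matrix shape")

    dose = _imputed_dosage(sub)
    n = dose.shape[0]
    p_hat = dose.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    nonzero = denom > 0
    excluded = retained[~nonzero]
    if excluded.size:
        log.info("pca: excluded %d zero-variance variants", excluded.size)
    x = (dose[:, nonzero] - 2.0 * p_hat[nonzero]) / denom[nonzero]

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    trace = float((x**2).sum()) / (n - 1)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    loadings = vt.T
    # sign convention: largest-magnitude loading positive per component
    for comp in range(k):
        j = np.argmax(np.abs(loadings[:, comp]))
        if loadings[j, comp] < 0:
            loadings[:, comp] *= -1
            u[:, comp] *= -1
    scores = u * s
    return PcaResult(
        eigenvalues=eigenvalues[:k],
        scores=scores,
        variance_fraction=eigenvalues[:k] / trace if trace > 0 else eigenvalues[:k],
        loadings=loadings,
        samples=list(sub.samples),
        used_variants=retained[nonzero],
        excluded_zero_variance=excluded,
    )
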