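"""Additive genomic relationship matrix (GRM) from biallelic markers.

Inbred (homozygous) lines are coded -1/+1 per marker, with 0 accepted for
residual heterozygotes.  The GRM is the VanRaden method-1 estimator:
column-center the marker matrix and scale by ``2 * sum_k p_k (1 - p_k)``,
where ``p_k`` is the allele frequency at marker k.  This is the realized
relatedness matrix used as the covariance structure of the polygenic
effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "KinshipMatrix",
    "compute_grm",
    "regularize",
    "read_markers",
    "read_kinship",
    "write_kinship",
]


@dataclass
class MarkerMatrix:
    """Lines x markers genotype matrix coded {-1, 0, +1}; NaN = missing."""

    line_ids: list[str]
    geno: np.ndarray
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=float)
        if self.geno.ndim != 2 or self.geno.shape[0] != len(self.line_ids):
            raise ValueError("geno must be (n_lines, n_markers)")
        valid = np.isnan(self.geno) | np.isin(self.geno, (-1.0, 0.0, 1.0))
        if not valid.all():
            raise ValueError("marker genotypes must be in {-1, 0, +1} or missing")


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix aligned with a line-ID list."""

    line_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.line_ids)
        if self.K.shape != (n, n):
            raise ValueError("K must be square and match line_ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")


def compute_grm(markers: MarkerMatrix) -> KinshipMatrix:
    """VanRaden method-1 GRM from a {-1,0,+1} marker matrix.

    Missing genotypes are mean-imputed per marker before centering;
    monomorphic markers are dropped (both counts are logged).
    """
    G = markers.geno.copy()
    n, _ = G.shape
    if n < 2:
        raise ValueError("need at least 2 lines")
    miss = np.isnan(G)
    if miss.any():
        col_mean = np.nanmean(G, axis=0)
        G[miss] = np.take(col_mean, np.nonzero(miss)[1])
        logger.info("mean-imputed %.3f%% missing genotypes", 100 * miss.mean())
    poly = G.std(axis=0) > 0
    n_drop = int((~poly).sum())
    if n_drop:
        logger.info("dropped %d monomorphic markers", n_drop)
    G = G[:, poly]
    if G.shape[1] == 0:
        raise ValueError("no polymorphic markers left")
    # allele frequency of the +1 allele from the {-1,0,+1} coding
    p = (G.mean(axis=0) + 1.0) / 2.0
    W = G - G.mean(axis=0)
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = (W @ W.T) / denom
    K = 0.5 * (K + K.T)
    return KinshipMatrix(list(markers.line_ids), K)


def regularize(
    km: KinshipMatrix, eps: float | None = None, max_tries: int = 8
) -> tuple[KinshipMatrix, float]:
    """Add diagonal jitter until a Cholesky factorization succeeds.

    ``eps`` defaults to 1e-6 times the mean diagonal and is escalated
    tenfold up to ``max_tries`` times.  Returns the loaded matrix and the
    jitter actually applied (recorded in fit manifests).
    """
    K = km.K
    if eps is not None and eps < 0:
        raise ValueError("eps must be non-negative")
    base = 1e-6 * float(np.mean(np.diag(K))) if eps is None else eps
    try:
        np.linalg.cholesky(K)
        if eps is None or eps == 0:
            return km, 0.0
    except np.linalg.LinAlgError:
        pass
    jitter = base if base > 0 else 1e-8
    for _ in range(max_tries):
        try:
            np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
            logger.info("kinship regularized with jitter %.3g", jitter)
            return KinshipMatrix(km.line_ids, K + jitter * np.eye(K.shape[0])), jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"kinship matrix not positive definite even after jitter {jitter:.3g}"
    )


def read_markers(path) -> MarkerMatrix:
    """Read a lines x markers TSV/CSV (first column line IDs, header row marker IDs)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return MarkerMatrix(
        [str(i) for i in df.index], df.to_numpy(dtype=float), list(df.columns)
    )


def write_kinship(km: KinshipMatrix, path) -> None:
    pd.DataFrame(km.K, index=km.line_ids, columns=km.line_ids).to_csv(
        path, float_format="%.10g"
    )


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError("kinship CSV row and column IDs disagree")
    return KinshipMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))
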