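"""Bivariate structural-equation model: data container and exact likelihood.

For each line i the recursive (strictly lower-triangular) system is

    y_P,i = x_P,i' beta_P + u_P,i + e_P,i
    y_A,i = L(y_P,i) * y_P,i + x_A,i' beta_A + u_A,i + e_A,i

with (e_P,i, e_A,i) ~ N2(0, R), polygenic effects (u_P, u_A) ~ MVN(0, G (x) K)
and L a cubic B-spline influence function of the observed phenological
phenotype.  Because the structural matrix is lower-triangular with unit
diagonal the transformation has unit Jacobian, so the joint density of
(y_P,i, y_A,i) is the bivariate normal density of the structural residuals.

Setting L = 0 gives the ordinary bivariate linear model (OLM) baseline: the
likelihoods nest exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .splines import KnotVector, SplineWeights, basis_matrix

__all__ = [
    "ModelKind",
    "ModelSpec",
    "BivariateDataset",
    "NSEParams",
    "center_phenotypes",
    "build_design",
    "dummy_code_haplotypes",
    "loglik_per_line",
    "per_line_logliks",
    "total_loglik",
    "bvn_loglik",
]

LOG2PI = float(np.log(2.0 * np.pi))


class ModelKind(str, Enum):
    NSE = "nse"
    OLM = "olm"
    NSE_ZERO_RESCOV = "nse-zero-rescov"


@dataclass
class ModelSpec:
    """Which model to fit and how many basis functions the spline uses.

    ``n_basis = M + 1`` where M defaults to 7 (eight basis functions); the
    zero-residual-covariance variant pins the off-diagonal of R at zero
    throughout sampling, the identifiability constraint for near-constant
    influences.
    """

    kind: ModelKind = ModelKind.NSE
    n_basis: int = 8

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)
        if self.kind is not ModelKind.OLM and self.n_basis < 5:
            raise ValueError("spline models need at least 5 basis functions")

    @property
    def has_spline(self) -> bool:
        return self.kind is not ModelKind.OLM

    @property
    def zero_rescov(self) -> bool:
        return self.kind is ModelKind.NSE_ZERO_RESCOV


@dataclass
class BivariateDataset:
    """Centered phenotypes, major-gene design matrices and kinship.

    ``y_P`` is the phenological trait (days, centered), ``y_A`` the
    influenced trait (cm, centered).  ``X_P`` holds an intercept column and
    the phenology-gene 0/1 dummies; ``X_A`` holds an intercept, the same
    phenology-gene dummies and any influenced-trait-specific gene dummies.
    The means removed by centering are retained for back-transformation.
    """

    line_ids: list[str]
    y_P: np.ndarray
    y_A: np.ndarray
    X_P: np.ndarray
    X_A: np.ndarray
    K: np.ndarray
    centering_means: tuple[float, float]
    X_P_cols: list[str] = field(default_factory=list)
    X_A_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y_P = np.asarray(self.y_P, dtype=float).ravel()
        self.y_A = np.asarray(self.y_A, dtype=float).ravel()
        self.X_P = np.atleast_2d(np.asarray(self.X_P, dtype=float))
        self.X_A = np.atleast_2d(np.asarray(self.X_A, dtype=float))
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.line_ids)
        for name, arr in (("y_P", self.y_P), ("y_A", self.y_A)):
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != n_lines {n}")
        for name, X in (("X_P", self.X_P), ("X_A", self.X_A)):
            if X.shape[0] != n:
                raise ValueError(f"{name} row count {X.shape[0]} != n_lines {n}")
        if self.K.shape != (n, n):
            raise ValueError("K shape mismatch")
        if abs(self.y_P.mean()) > 1e-8 or abs(self.y_A.mean()) > 1e-8:
            raise ValueError("phenotypes must be centered (use center_phenotypes)")
        if not self.X_P_cols:
            self.X_P_cols = [f"xP{j}" for j in range(self.X_P.shape[1])]
        if not self.X_A_cols:
            self.X_A_cols = [f"xA{j}" for j in range(self.X_A.shape[1])]

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


@dataclass
class NSEParams:
    """Full parameter state of the structural model.

    ``spline`` is None for the OLM.  G and R are the 2x2 genetic and
    residual covariance matrices across the two traits.
    """

    beta_P: np.ndarray
    beta_A: np.ndarray
    u_P: np.ndarray
    u_A: np.ndarray
    G: np.ndarray
    R: np.ndarray
    spline: SplineWeights | None = None

    def __post_init__(self) -> None:
        for name in ("beta_P", "beta_A", "u_P", "u_A"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        self.G = np.asarray(self.G, dtype=float).reshape(2, 2)
        self.R = np.asarray(self.R, dtype=float).reshape(2, 2)


def center_phenotypes(
    raw_P: np.ndarray, raw_A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Center both traits to mean zero; returns the removed means."""
    raw_P = np.asarray(raw_P, dtype=float).ravel()
    raw_A = np.asarray(raw_A, dtype=float).ravel()
    if raw_P.size != raw_A.size:
        raise ValueError("trait vectors must have equal length")
    if raw_P.size < 2:
        raise ValueError("need at least 2 lines")
    if not (np.all(np.isfinite(raw_P)) and np.all(np.isfinite(raw_A))):
        raise ValueError("phenotypes contain non-finite values")
    m_P, m_A = float(raw_P.mean()), float(raw_A.mean())
    return raw_P - m_P, raw_A - m_A, (m_P, m_A)


def dummy_code_haplotypes(haps: pd.Series, reference: str) -> pd.DataFrame:
    """k-1 dummy columns for a multi-allelic locus versus a reference allele."""
    haps = haps.astype(str)
    levels = [h for h in pd.unique(haps) if h != reference]
    if len(levels) == len(pd.unique(haps)):
        raise ValueError(f"reference allele {reference!r} not present")
    out = pd.DataFrame(index=haps.index)
    for lev in sorted(levels):
        out[f"{haps.name}.{lev}"] = (haps == lev).astype(int)
    return out


def build_design(
    gene_table: pd.DataFrame,
    manifest: dict[str, str],
    reference_line: str,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Build the two fixed-effect design matrices from 0/1 gene dummies.

    ``manifest`` assigns each gene column to the phenological trait ("P"),
    the influenced trait only ("A"), or "both".  Phenology genes enter both
    designs (their carriers differ in the influenced trait through both the
    direct path and the phenology path); "A" columns enter only ``X_A``.
    The reference line must carry the reference allele everywhere, i.e. its
    genotype row is all zeros.
    """
    ids = [str(i) for i in gene_table.index]
    if str(reference_line) not in ids:
        raise ValueError(f"reference line {reference_line!r} not in gene table")
    vals = gene_table.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = gene_table.columns[(~np.isin(vals, (0, 1))).any(axis=0)]
        raise ValueError(f"non-0/1 entries in gene columns: {list(bad)}")
    ref_row = gene_table.loc[str(reference_line)]
    if ref_row.to_numpy().any():
        raise ValueError("reference line must be all-zero in genotype columns")
    unknown = set(gene_table.columns) - set(manifest)
    if unknown:
        raise ValueError(f"gene columns missing from manifest: {sorted(unknown)}")
    p_cols = [c for c in gene_table.columns if manifest[c].upper() in ("P", "BOTH")]
    a_only = [c for c in gene_table.columns if manifest[c].upper() == "A"]
    n = len(ids)
    X_P = np.column_stack([np.ones(n)] + [gene_table[c].to_numpy(float) for c in p_cols])
    X_A = np.column_stack(
        [np.ones(n)] + [gene_table[c].to_numpy(float) for c in p_cols + a_only]
    )
    return X_P, X_A, ["intercept"] + p_cols, ["intercept"] + p_cols + a_only


def _chol2(R: np.ndarray) -> tuple[float, float, float]:
    """Cholesky of a 2x2 SPD matrix; raises if not PD."""
    a, b, c = R[0, 0], R[0, 1], R[1, 1]
    det = a * c - b * b
    if a <= 0 or det <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(c - l21 * l21)
    return l11, l21, l22


def bvn_loglik(e: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Bivariate normal log-density of residual rows ``e`` (n, 2) under cov R."""
    e = np.atleast_2d(e)
    a, b, c = R[0, 0], R[0, 1], R[1, 1]
    det = a * c - b * b
    if a <= 0 or det <= 0:
        raise np.linalg.LinAlgError("R not positive definite")
    i00, i01, i11 = c / det, -b / det, a / det
    q = i00 * e[:, 0] ** 2 + 2 * i01 * e[:, 0] * e[:, 1] + i11 * e[:, 1] ** 2
    return -LOG2PI - 0.5 * np.log(det) - 0.5 * q


def structural_residuals(
    data: BivariateDataset, params: NSEParams, kv: KnotVector | None
) -> np.ndarray:
    """Residual matrix (n, 2) of the structural equations at the given state."""
    e_P = data.y_P - data.X_P @ params.beta_P - params.u_P
    mean_A = data.X_A @ params.beta_A + params.u_A
    if params.spline is not None:
        if kv is None:
            raise ValueError("knot vector required when spline weights are present")
        if np.any(data.y_P < kv.lower) or np.any(data.y_P > kv.upper):
            raise ValueError("phenological phenotypes outside the knot range")
        L = basis_matrix(kv, data.y_P) @ params.spline.P
        mean_A = mean_A + L * data.y_P
    e_A = data.y_A - mean_A
    return np.column_stack([e_P, e_A])


def per_line_logliks(
    data: BivariateDataset, params: NSEParams, kv: KnotVector | None = None
) -> np.ndarray:
    """Per-line log-likelihood vector (the WAIC pointwise contributions)."""
    return bvn_loglik(structural_residuals(data, params, kv), params.R)


def loglik_per_line(
    data: BivariateDataset, params: NSEParams, kv: KnotVector | None, i: int
) -> float:
    """Log joint density of (y_P[i], y_A[i]) at the given parameter state."""
    return float(per_line_logliks(data, params, kv)[i])


def total_loglik(
    data: BivariateDataset, params: NSEParams, kv: KnotVector | None = None
) -> float:
    """Sum of the per-line log-likelihoods (the Metropolis/WAIC workhorse)."""
    return float(per_line_logliks(data, params, kv).sum())
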