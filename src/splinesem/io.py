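"""File I/O and run configuration.

Canonical on-disk dialect is TSV with explicit headers (CSV accepted on
read, chosen by extension); numeric output uses 10 significant digits.
A run is fully described by a YAML config file; every key can be
overridden by a CLI flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import read_kinship, read_markers, compute_grm
from .model import BivariateDataset, build_design, center_phenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_phenotypes",
    "read_gene_table",
    "read_manifest",
    "read_inputs",
    "write_table",
]

FLOAT_FMT = "%.10g"


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class RunConfig:
    """Paths and settings for a fit run."""

    phenotypes: str
    genes: str
    gene_manifest: str
    markers: str | None = None
    kinship: str | None = None
    reference_line: str | None = None
    model: str = "nse"
    n_basis: int = 8
    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    sigma_prop2: float = 0.04
    seed: int = 0
    out_dir: str = "fit_out"

    def __post_init__(self) -> None:
        if (self.markers is None) == (self.kinship is None):
            raise ValueError("provide exactly one of markers / kinship")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: line_id, trait_P, trait_A (TSV/CSV)."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 3:
        raise ValueError("phenotype file needs line_id + two trait columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate line IDs in phenotype file: {dups}")
    for col in df.columns[:2]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric phenotype at line {row!r}, column {col!r}")
        df[col] = vals
    return df.iloc[:, :2]


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError("duplicate line IDs in gene table")
    return df


def read_manifest(path) -> dict[str, str]:
    """Two-column table assigning each gene column to trait P, A or both."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError("manifest needs columns: column, trait")
    man = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    for col, role in man.items():
        if role.upper() not in ("P", "A", "BOTH"):
            raise ValueError(f"manifest role for {col!r} must be P, A or both")
    return man


def read_inputs(config: RunConfig) -> BivariateDataset:
    """Parse, align and assemble the dataset for a fit.

    Line IDs are intersected across the phenotype, gene and kinship/marker
    files (phenotype order preserved; dropped lines logged); lines missing
    either trait are removed (complete-case); phenotypes are centered on
    the retained lines.
    """
    pheno = read_phenotypes(config.phenotypes)
    genes = read_gene_table(config.genes)
    manifest = read_manifest(config.gene_manifest)
    if config.kinship is not None:
        km = read_kinship(config.kinship)
    else:
        km = compute_grm(read_markers(config.markers))
    k_index = {lid: j for j, lid in enumerate(km.line_ids)}
    keep = [
        lid
        for lid in pheno.index
        if lid in genes.index and lid in k_index and not pheno.loc[lid].isna().any()
    ]
    dropped = [lid for lid in pheno.index if lid not in keep]
    if dropped:
        logger.info("dropped %d lines (missing data or unmatched IDs): %s",
                    len(dropped), dropped[:10])
    if len(keep) < 10:
        raise ValueError(f"only {len(keep)} aligned complete-case lines (<10)")
    pheno = pheno.loc[keep]
    genes = genes.loc[keep]
    idx = [k_index[lid] for lid in keep]
    K = km.K[np.ix_(idx, idx)]
    ref = config.reference_line
    if ref is None:
        zero_rows = genes.index[(genes == 0).all(axis=1)]
        if len(zero_rows) == 0:
            raise ValueError("no all-zero gene row; specify reference_line")
        ref = str(zero_rows[0])
    X_P, X_A, cols_P, cols_A = build_design(genes, manifest, ref)
    y_P, y_A, means = center_phenotypes(
        pheno.iloc[:, 0].to_numpy(float), pheno.iloc[:, 1].to_numpy(float)
    )
    return BivariateDataset(
        line_ids=keep,
        y_P=y_P,
        y_A=y_A,
        X_P=X_P,
        X_A=X_A,
        K=K,
        centering_means=means,
        X_P_cols=cols_P,
        X_A_cols=cols_A,
    )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep=_sep(path), index=index, float_format=FLOAT_FMT)
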