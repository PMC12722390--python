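"""Cell-inclusion gate, normalisation and non-epithelial marker filtering.

The inclusion gate keeps a cell when its sequencing depth is strictly above
``min_depth`` (default 8750 UMIs), its expressed-gene count lies inside an
inclusive range (default 2000-8000) and its mitochondrial and ribosomal
percentages are strictly below their caps (defaults 15% and 45%).
Mitochondrial and ribosomal genes are removed from the matrix afterwards.

Non-epithelial cells (fibroblasts, immune cells) are removed by a density
rule on normalised expression of marker genes (defaults Col1a2, Pdgfra,
Ptprc): a cell is excluded when, for any marker, its expression lies
strictly above the first local minimum of the marker's kernel density
estimate to the right of the global (zero-inflation) mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde

__all__ = [
    "QCThresholds",
    "MarkerFilterConfig",
    "apply_qc_filters",
    "normalize_counts",
    "epithelial_marker_filter",
]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusion bounds: depth bound exclusive ("over"), gene range inclusive
    ("between"), percentage caps exclusive ("lower than")."""

    min_depth: int = 8750
    gene_range: tuple[int, int] = (2000, 8000)
    max_mito_pct: float = 15.0
    max_ribo_pct: float = 45.0

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")
        if self.gene_range[0] > self.gene_range[1]:
            raise ValueError("gene_range lower bound exceeds upper bound")
        for pct in (self.max_mito_pct, self.max_ribo_pct):
            if not 0.0 < pct <= 100.0:
                raise ValueError("percentage caps must lie in (0, 100]")


@dataclass(frozen=True)
class MarkerFilterConfig:
    marker_genes: tuple[str, ...] = ("Col1a2", "Pdgfra", "Ptprc")
    kde_bandwidth_rule: str = "silverman"
    grid_points: int = 512
    exclusion_mode: str = "any-marker"

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError("marker list must be non-empty")
        if self.exclusion_mode != "any-marker":
            raise ValueError("only 'any-marker' exclusion is supported")


def _as_dense_col(X, j: int) -> np.ndarray:
    col = X[:, j]
    return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()


def compute_cell_qc(
    adata: ad.AnnData, mito_genes: Sequence[str], ribo_genes: Sequence[str]
) -> pd.DataFrame:
    """Per-cell QC metrics (depth, expressed genes, mito%, ribo%)."""
    genes = adata.var_names
    for name, gene_set in (("mito", mito_genes), ("ribo", ribo_genes)):
        unknown = set(gene_set) - set(genes)
        if unknown:
            raise ValueError(f"unknown {name} genes: {sorted(unknown)}")
    X = sp.csr_matrix(adata.X)
    depth = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito_idx = genes.get_indexer(list(mito_genes))
    ribo_idx = genes.get_indexer(list(ribo_genes))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(
            depth > 0,
            100.0 * np.asarray(X[:, mito_idx].sum(axis=1)).ravel() / np.maximum(depth, 1),
            0.0,
        )
        pct_ribo = np.where(
            depth > 0,
            100.0 * np.asarray(X[:, ribo_idx].sum(axis=1)).ravel() / np.maximum(depth, 1),
            0.0,
        )
    return pd.DataFrame(
        {
            "depth": depth.astype(int),
            "n_genes": n_genes.astype(int),
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
        },
        index=adata.obs_names,
    )


def apply_qc_filters(
    adata: ad.AnnData,
    mito_genes: Sequence[str],
    ribo_genes: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Gate cells on depth/genes/mito%/ribo%, then drop mito+ribo genes.

    Returns the filtered AnnData (kept cells, mito/ribo genes removed) and
    the full per-cell QC table with a boolean ``kept`` column.
    """
    qc = compute_cell_qc(adata, mito_genes, ribo_genes)
    t = thresholds
    kept = (
        (qc["depth"] > t.min_depth)
        & (qc["n_genes"] >= t.gene_range[0])
        & (qc["n_genes"] <= t.gene_range[1])
        & (qc["pct_mito"] < t.max_mito_pct)
        & (qc["pct_ribo"] < t.max_ribo_pct)
    )
    qc["kept"] = kept
    drop = set(mito_genes) | set(ribo_genes)
    keep_genes = [g for g in adata.var_names if g not in drop]
    out = adata[kept.to_numpy(), keep_genes].copy()
    return out, qc


def normalize_counts(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size normalisation to ``scale`` counts per cell, then ln(1+x).

    A documented stand-in for variance-stabilising normalisation: per cell,
    counts are scaled to a common total and natural-log1p transformed.
    Zero-depth cells come out all-zero and are flagged in
    ``obs["zero_depth"]``.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    zero = depth == 0
    sf = np.divide(scale, depth, out=np.zeros_like(depth), where=~zero)
    Xn = sp.diags(sf) @ X
    Xn.data = np.log1p(Xn.data)
    out = adata.copy()
    out.layers["counts"] = adata.X
    out.X = sp.csr_matrix(Xn)
    out.obs["zero_depth"] = zero
    return out


def _first_local_minimum_threshold(
    x: np.ndarray, bandwidth_rule: str, grid_points: int
) -> float | None:
    """Expression value of the first KDE local minimum right of the global
    mode, or None when no local minimum exists (e.g. unimodal density)."""
    if np.allclose(x, x[0]):
        return None
    try:
        kde = gaussian_kde(x, bw_method=bandwidth_rule)
    except np.linalg.LinAlgError:
        return None
    grid = np.linspace(0.0, float(x.max()), grid_points)
    dens = kde(grid)
    mode = int(np.argmax(dens))
    interior = dens[1:-1]
    is_min = (interior < dens[:-2]) & (interior < dens[2:])
    min_pos = np.flatnonzero(is_min) + 1
    min_pos = min_pos[min_pos > mode]
    if min_pos.size == 0:
        return None
    return float(grid[min_pos[0]])


def epithelial_marker_filter(
    adata: ad.AnnData,
    config: MarkerFilterConfig = MarkerFilterConfig(),
) -> tuple[ad.AnnData, dict[str, float | None]]:
    """Remove cells expressing any non-epithelial marker above its density
    threshold.

    For each marker gene a Gaussian KDE (Silverman bandwidth) over all
    cells' normalised expression is evaluated on a fixed grid; the threshold
    is the first local minimum right of the global mode.  Cells strictly
    above the threshold for ANY marker are excluded.  Markers without a
    local minimum exclude no one.
    """
    missing = [g for g in config.marker_genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    X = adata.X
    exclude = np.zeros(adata.n_obs, dtype=bool)
    thresholds: dict[str, float | None] = {}
    for gene in config.marker_genes:
        j = adata.var_names.get_loc(gene)
        x = _as_dense_col(X, j)
        thr = _first_local_minimum_threshold(
            x, config.kde_bandwidth_rule, config.grid_points
        )
        thresholds[gene] = thr
        if thr is not None:
            exclude |= x > thr
    return adata[~exclude].copy(), thresholds
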