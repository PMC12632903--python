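"""Cell/gene quality control and log1p normalisation for RNA and ADT counts.

QC drops low-count cells, high-mitochondrial cells and rarely detected
genes, in that order, and reports what each step removed.  Normalisation
rescales each cell to a common target sum before log1p; the same transform
is applied to RNA and ADT modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = ["QCReport", "qc_filter", "lognormalize", "mito_fraction"]


def _row_sums(x) -> np.ndarray:
    return np.asarray(x.sum(axis=1)).ravel()


def mito_fraction(adata: ad.AnnData, mito_prefix: str = "MT-") -> np.ndarray:
    """Per-cell fraction of counts on mitochondrially encoded genes (by name prefix)."""
    is_mito = adata.var_names.str.startswith(mito_prefix)
    totals = _row_sums(adata.X)
    mito = _row_sums(adata[:, is_mito].X) if is_mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    cells_removed_low_count: int
    cells_removed_mito: int
    genes_removed_min_cells: int
    n_cells_out: int
    n_genes_out: int

    def __str__(self) -> str:
        return (
            f"QC: {self.n_cells_in} cells x {self.n_genes_in} genes -> "
            f"{self.n_cells_out} x {self.n_genes_out} "
            f"(-{self.cells_removed_low_count} low-count cells, "
            f"-{self.cells_removed_mito} high-mito cells, "
            f"-{self.genes_removed_min_cells} rare genes)"
        )


def qc_filter(
    adata: ad.AnnData,
    min_counts: int = 200,
    max_mito: float = 0.08,
    min_cells_per_gene: int = 10,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, QCReport]:
    """Filter cells then genes; thresholds are min_counts (>=), max_mito (<=, i.e.
    a cell at exactly the threshold is retained) and min_cells_per_gene (>=)."""
    n_cells_in, n_genes_in = adata.shape
    totals = _row_sums(adata.X)
    keep_counts = totals >= min_counts
    adata = adata[keep_counts].copy()
    cells_low = int(n_cells_in - adata.n_obs)

    frac = mito_fraction(adata, mito_prefix)
    keep_mito = frac <= max_mito
    n_before = adata.n_obs
    adata = adata[keep_mito].copy()
    adata.obs["total_counts"] = _row_sums(adata.X)
    adata.obs["mito_fraction"] = frac[keep_mito]
    cells_mito = int(n_before - adata.n_obs)
    if adata.n_obs == 0:
        raise ValueError("QC removed every cell")

    x = adata.X
    detected = np.asarray((x > 0).sum(axis=0)).ravel()
    keep_genes = detected >= min_cells_per_gene
    n_genes_before = adata.n_vars
    adata = adata[:, keep_genes].copy()
    genes_removed = int(n_genes_before - adata.n_vars)

    report = QCReport(
        n_cells_in=n_cells_in,
        n_genes_in=n_genes_in,
        cells_removed_low_count=cells_low,
        cells_removed_mito=cells_mito,
        genes_removed_min_cells=genes_removed,
        n_cells_out=adata.n_obs,
        n_genes_out=adata.n_vars,
    )
    return adata, report


def lognormalize(adata: ad.AnnData, target_sum: float = 10_000.0,
                 layer: str = "lognorm") -> ad.AnnData:
    """log1p-normalise each cell to ``target_sum``: log(1 + c * S / total).

    Stores the result in ``adata.layers[layer]`` (raw counts stay in .X) and
    returns the same object.  Conservation: sum of expm1(values) per cell
    equals ``target_sum``.
    """
    totals = _row_sums(adata.X)
    if (totals <= 0).any():
        raise ValueError("zero-total cell: run qc_filter first")
    x = adata.X
    if sp.issparse(x):
        norm = x.multiply((target_sum / totals)[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(np.asarray(x) * (target_sum / totals)[:, None])
    adata.layers[layer] = norm
    adata.uns["lognorm_target_sum"] = float(target_sum)
    return adata
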