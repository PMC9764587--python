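"""QC filtering, normalization, expressed-gene sets, and pseudobulk.

Cells are removed when they have fewer than 301 expressed genes or more
than 30% of UMIs from mitochondrial genes; the boundary cells (exactly 301
genes, exactly 30% mito) are kept. Normalization is counts-per-``scale``
followed by natural log1p. The "expressed gene set" of a cell type is the
set of genes detected in strictly more than 10% of its cells — it serves
both as the enrichment background and as the denominator of the crosstalk
proportion. Pseudobulk collapses cells to one mean profile per
(individual, cell type).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "QCThresholds",
    "qc_filter",
    "normalize",
    "expressed_gene_set",
    "PseudobulkCube",
    "individual_pseudobulk",
]


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 301
    max_mito_fraction: float = 0.30

    def __post_init__(self):
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()):
    """Remove cells with < ``min_genes`` expressed genes or > ``max_mito_fraction``
    mitochondrial UMI fraction.

    Returns ``(filtered AnnData, per-cell QC report DataFrame)``. The report
    covers every input cell with its expressed-gene count, mito fraction and
    pass/fail flag. The gene set is unchanged.
    """
    if adata.n_obs == 0:
        raise ValueError("empty matrix: no cells to filter")
    if "mito" not in adata.var:
        raise ValueError("missing mito flags in .var['mito']")
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    mito_total = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 1.0)
    keep = (n_genes >= thresholds.min_genes) & (mito_frac <= thresholds.max_mito_fraction)
    report = pd.DataFrame(
        {
            "n_genes_expressed": n_genes,
            "total_umis": total.astype(int),
            "mito_fraction": mito_frac,
            "passed_qc": keep,
        },
        index=adata.obs_names,
    )
    return adata[keep].copy(), report


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize to ``scale`` counts per cell, then natural log1p.

    x_gc = log(1 + count_gc * scale / total_c). Raw counts are preserved in
    ``.layers['counts']``. Cells with zero total raise, since they cannot
    have survived QC.
    """
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ValueError("cell with zero total counts; run qc_filter first")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    Xn = X.astype(np.float64).multiply(scale / total[:, None]).tocsr()
    Xn.data = np.log1p(Xn.data)
    out.X = Xn
    out.uns["normalization"] = {"scale": scale, "log": "natural log1p"}
    return out


def expressed_gene_set(adata: ad.AnnData, cell_type: str, min_fraction: float = 0.10) -> set:
    """Genes detected in strictly more than ``min_fraction`` of the cell
    type's cells. ``min_fraction=0`` therefore means "detected at least once"."""
    mask = (adata.obs["cell_type"] == cell_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"cell type {cell_type!r} has no cells")
    X = adata.X[mask]
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    det_frac = np.asarray((X > 0).sum(axis=0)).ravel() / mask.sum()
    return set(np.asarray(adata.var_names)[det_frac > min_fraction])


class PseudobulkCube:
    """individual x cell_type x gene mean of normalized expression.

    Absent (individual, cell type) combinations are flagged via
    ``present`` / ``cell_counts == 0`` rather than stored as zeros.
    """

    def __init__(self, values, cell_counts, individuals, cell_types, genes):
        self.values = values  # (n_ind, n_ct, n_genes), NaN where absent
        self.cell_counts = cell_counts  # (n_ind, n_ct) ints
        self.individuals = list(individuals)
        self.cell_types = list(cell_types)
        self.genes = list(genes)
        self._ind_idx = {v: i for i, v in enumerate(self.individuals)}
        self._ct_idx = {v: i for i, v in enumerate(self.cell_types)}
        self._gene_idx = {v: i for i, v in enumerate(self.genes)}

    @property
    def present(self):
        return self.cell_counts > 0

    def profile(self, individual: str, cell_type: str):
        """Mean expression vector for one (individual, cell type); None if absent."""
        i, j = self._ind_idx[individual], self._ct_idx[cell_type]
        if self.cell_counts[i, j] == 0:
            return None
        return self.values[i, j]

    def gene_matrix(self, cell_type: str, genes) -> pd.DataFrame:
        """individuals x genes matrix for one cell type (NaN rows where absent)."""
        j = self._ct_idx[cell_type]
        gi = [self._gene_idx[g] for g in genes]
        return pd.DataFrame(
            self.values[:, j][:, gi], index=self.individuals, columns=list(genes)
        )


def individual_pseudobulk(adata: ad.AnnData) -> PseudobulkCube:
    """Arithmetic mean of normalized expression per (individual, cell type).

    Cell order does not matter; combinations with no cells are flagged
    absent (NaN values, zero cell count).
    """
    individuals = list(pd.unique(adata.obs["individual"]))
    cell_types = list(pd.unique(adata.obs["cell_type"]))
    genes = list(adata.var_names)
    values = np.full((len(individuals), len(cell_types), len(genes)), np.nan)
    counts = np.zeros((len(individuals), len(cell_types)), dtype=int)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    ind_codes = pd.Categorical(adata.obs["individual"], categories=individuals).codes
    ct_codes = pd.Categorical(adata.obs["cell_type"], categories=cell_types).codes
    for i in range(len(individuals)):
        for j in range(len(cell_types)):
            mask = (ind_codes == i) & (ct_codes == j)
            n = int(mask.sum())
            counts[i, j] = n
            if n:
                values[i, j] = np.asarray(X[mask].mean(axis=0)).ravel()
    return PseudobulkCube(values, counts, individuals, cell_types, genes)
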