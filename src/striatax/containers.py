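"""Core in-memory containers.

``CountMatrix`` holds sparse cell x gene integer counts with per-cell
metadata (sample, region) and derived QC metrics; it converts to and
from :class:`anndata.AnnData` so downstream tooling interoperates with
the scverse ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

MITO_PREFIX = "MT-"


@dataclass
class CountMatrix:
    """Sparse cell x gene raw count matrix with cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows (CSR recommended).
    cell_ids
        Unique cell barcodes/identifiers.
    gene_names
        Gene symbols; mitochondrial genes are recognized by the
        ``MT-`` prefix.
    cell_meta
        Per-cell frame indexed like ``cell_ids`` with at least columns
        ``sample_id`` and ``region``.
    """

    counts: sp.spmatrix
    cell_ids: np.ndarray
    gene_names: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index = self.cell_ids

    # -- derived per-cell metrics -------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes_total(self) -> int:
        return self.counts.shape[1]

    @property
    def n_umis(self) -> np.ndarray:
        """Total counts per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def n_genes(self) -> np.ndarray:
        """Number of genes with nonzero counts per cell."""
        return np.diff(self.counts.indptr)

    @property
    def mito_mask(self) -> np.ndarray:
        return np.array([g.startswith(MITO_PREFIX) for g in self.gene_names])

    @property
    def mito_fraction(self) -> np.ndarray:
        """Share of each cell's counts falling on MT- genes."""
        tot = self.n_umis.astype(float)
        mito = np.asarray(self.counts[:, self.mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / np.maximum(tot, 1), 0.0)
        return frac

    # -- subsetting ----------------------------------------------------
    def cell_index(self, cell_ids) -> np.ndarray:
        pos = pd.Index(self.cell_ids).get_indexer(cell_ids)
        if (pos < 0).any():
            missing = np.asarray(cell_ids)[pos < 0][:5]
            raise KeyError(f"unknown cell ids: {list(missing)}")
        return pos

    def subset_cells(self, cell_ids) -> "CountMatrix":
        idx = self.cell_index(cell_ids)
        return CountMatrix(
            self.counts[idx],
            self.cell_ids[idx],
            self.gene_names,
            self.cell_meta.iloc[idx],
        )

    def gene_index(self, names) -> np.ndarray:
        pos = pd.Index(self.gene_names).get_indexer(names)
        if (pos < 0).any():
            missing = np.asarray(names)[pos < 0][:5]
            raise KeyError(f"unknown genes: {list(missing)}")
        return pos

    # -- interop -------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )

    @classmethod
    def from_anndata(cls, adata) -> "CountMatrix":
        return cls(
            sp.csr_matrix(adata.X),
            np.asarray(adata.obs_names),
            np.asarray(adata.var_names),
            adata.obs,
        )
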