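"""In-memory containers for paired expression / receptor / protein data.

The central object is :class:`CellDataset`, a thin bundle of an
:class:`anndata.AnnData` count matrix (cells x genes), an AIRR-style
rearrangement table, and a per-cell surface-protein intensity table, all
joined on the cell barcode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Columns required of an AIRR rearrangement table.
AIRR_COLUMNS = ["cell_id", "locus", "v_call", "j_call", "junction_aa", "productive"]


@dataclass
class CellDataset:
    """Joined single-cell expression, receptor and protein data.

    Parameters
    ----------
    adata
        Cells x genes raw counts, with per-cell metadata (cluster label,
        sample, timepoint, ...) in ``adata.obs``.
    airr
        AIRR rearrangement table (one row per chain), restricted to cell
        barcodes present in ``adata.obs_names``.
    protein
        Per-cell surface-protein intensities, indexed by cell barcode.
    """

    adata: ad.AnnData
    airr: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=AIRR_COLUMNS))
    protein: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def gene_names(self) -> pd.Index:
        return self.adata.var_names

    def counts(self) -> sp.csr_matrix:
        """Raw counts as a CSR matrix (cells x genes)."""
        X = self.adata.X
        if sp.issparse(X):
            return X.tocsr()
        return sp.csr_matrix(X)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CellDataset({self.n_cells} cells x {self.n_genes} genes, "
            f"{len(self.airr)} chains, {self.protein.shape[1]} protein markers)"
        )


def normalize_log1p(dataset_or_adata, target_sum: float = 1e4) -> np.ndarray:
    """Depth-normalize counts to ``target_sum`` per cell and log1p-transform.

    Returns a dense cells x genes float array of log-normalized expression.
    Cells with zero total count are left as all-zero rows.
    """
    adata = dataset_or_adata.adata if isinstance(dataset_or_adata, CellDataset) else dataset_or_adata
    X = adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    X = X.astype(float)
    totals = X.sum(axis=1)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    return np.log1p(X * scale[:, None])
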