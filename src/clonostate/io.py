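"""Readers for the on-disk dataset layout (MTX triplet + TSV/CSV sides).

The expression matrix is stored genes x cells (rows = features), the common
10x triplet dialect; :func:`read_dataset` transposes to the cells x genes
orientation used in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import CellDataset

logger = logging.getLogger(__name__)


class DatasetReadError(ValueError):
    """Malformed or inconsistent on-disk dataset."""


def _read_mtx(path: Path) -> sp.csr_matrix:
    if path.stat().st_size == 0:
        raise DatasetReadError(f"{path}: empty MatrixMarket file")
    try:
        M = scipy.io.mmread(str(path))
    except ValueError as exc:
        raise DatasetReadError(f"{path}: malformed MatrixMarket header ({exc})") from exc
    return sp.csr_matrix(M)


def _read_column_file(path: Path) -> pd.DataFrame:
    """Headerless TSV; an empty file is a valid zero-row axis."""
    if path.stat().st_size == 0:
        return pd.DataFrame({0: pd.Series([], dtype=str)})
    return pd.read_csv(path, sep="\t", header=None)


def read_dataset(directory) -> CellDataset:
    """Read a dataset directory written by ``write_dataset``.

    Joins expression, metadata, protein and AIRR tables on the cell
    barcode. AIRR rows whose barcode is absent from the expression matrix
    are dropped with a logged count; duplicate barcodes raise.
    """
    directory = Path(directory)
    M = _read_mtx(directory / "matrix.mtx")  # genes x cells
    features = _read_column_file(directory / "features.tsv")
    barcodes = _read_column_file(directory / "barcodes.tsv")[0].astype(str)
    if barcodes.duplicated().any():
        dupes = barcodes[barcodes.duplicated()].tolist()[:5]
        raise DatasetReadError(f"duplicate cell barcodes: {dupes}")
    genes = features[0].astype(str)
    if genes.duplicated().any():
        raise DatasetReadError("duplicate gene identifiers in features.tsv")
    if M.shape != (len(genes), len(barcodes)):
        raise DatasetReadError(
            f"matrix.mtx is {M.shape} but features/barcodes declare "
            f"({len(genes)}, {len(barcodes)})"
        )
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    meta_path = directory / "metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col="cell_id")
        obs = obs.join(meta, how="left")
    adata = ad.AnnData(
        X=M.T.tocsr().astype(np.int32),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )

    airr_path = directory / "airr_rearrangements.tsv"
    if airr_path.exists() and airr_path.stat().st_size > 0:
        airr = pd.read_csv(airr_path, sep="\t", dtype={"cell_id": str})
        known = airr["cell_id"].isin(set(barcodes))
        n_dropped = int((~known).sum())
        if n_dropped:
            logger.info("dropped %d AIRR rows with barcodes absent from the matrix", n_dropped)
        airr = airr[known].reset_index(drop=True)
    else:
        airr = pd.DataFrame()

    protein_path = directory / "protein.csv"
    if protein_path.exists() and protein_path.stat().st_size > 0:
        protein = pd.read_csv(protein_path, index_col="cell_id")
        protein = protein.reindex(barcodes)
    else:
        protein = pd.DataFrame(index=obs.index)

    return CellDataset(adata=adata, airr=airr, protein=protein)
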