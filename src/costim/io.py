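"""Reading and writing the standard on-disk formats.

Count matrices travel as a 10x-style MatrixMarket triple (``matrix.mtx``
with 1-based indices, genes as rows and cells as columns, plus
``barcodes.tsv`` and ``features.tsv``) or as a dense TSV; per-cell
condition labels come from a two-column TSV. Secretion chips are plain
TSV tables with ``well_id, row, col, cell_count`` followed by one column
per analyte.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core_programs import CONDITION_KEY
from .secretion import WELL_COLUMNS, SecretionChip


def write_counts_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write a genes x cells MatrixMarket triple (matrix.mtx,
    barcodes.tsv, features.tsv) plus conditions.tsv when present."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sparse.csc_matrix(X.T if not sparse.issparse(X) else X.T)
    spio.mmwrite(str(outdir / "matrix.mtx"), mat.astype(np.int64))
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      header=False, index=False)
    if CONDITION_KEY in adata.obs:
        adata.obs[CONDITION_KEY].astype(str).rename("condition").to_csv(
            outdir / "conditions.tsv", sep="\t", header=False
        )


def read_counts_mtx(
    indir: str | Path, conditions: str | Path | None = None
) -> ad.AnnData:
    """Read a MatrixMarket triple back into an AnnData (cells x genes)."""
    indir = Path(indir)
    mat = spio.mmread(str(indir / "matrix.mtx"))
    counts = np.asarray(sparse.csr_matrix(mat).T.todense()).astype(np.int64)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=barcodes.astype(str)),
        var=pd.DataFrame(index=features.astype(str)),
    )
    cond_path = Path(conditions) if conditions else indir / "conditions.tsv"
    if cond_path.exists():
        attach_conditions(adata, cond_path)
    return adata


def read_counts_tsv(path: str | Path,
                    conditions: str | Path | None = None) -> ad.AnnData:
    """Read a dense cells x genes TSV (cell ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    adata = ad.AnnData(
        X=df.to_numpy(np.int64),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )
    if conditions:
        attach_conditions(adata, conditions)
    return adata


def attach_conditions(adata: ad.AnnData, path: str | Path) -> None:
    """Attach per-cell condition labels from a 2-column TSV
    (cell_id, condition); every cell must be covered."""
    cond = pd.read_csv(path, sep="\t", header=None, index_col=0)[1]
    cond.index = cond.index.astype(str)
    missing = adata.obs_names.difference(cond.index)
    if len(missing):
        raise ValueError(f"conditions missing for cells: {list(missing[:5])}")
    adata.obs[CONDITION_KEY] = cond.reindex(adata.obs_names).astype(str).to_numpy()


def write_chip(chip: SecretionChip, path: str | Path) -> None:
    chip.wells.to_csv(path, sep="\t", index=False)


def read_chip(path: str | Path, normalized: bool = False) -> SecretionChip:
    """Read a chip TSV; analyte columns are everything after the four
    fixed well columns."""
    wells = pd.read_csv(path, sep="\t")
    analytes = [c for c in wells.columns if c not in WELL_COLUMNS]
    if not analytes:
        raise ValueError("chip table has no analyte columns")
    return SecretionChip(wells=wells, analytes=analytes, normalized=normalized)
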