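"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as 10x-style Matrix Market triplets
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) or as dense TSV;
metadata, TCR chains, marker tables and homology maps as TSV with header;
gene sets as GMT.  Matrix Market I/O goes through ``scipy.io``.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

__all__ = [
    "write_10x_dir",
    "read_10x_dir",
    "write_dense_tsv",
    "read_dense_tsv",
    "read_tcr_tsv",
    "write_tsv",
]


def write_10x_dir(adata: ad.AnnData, outdir) -> Path:
    """10x triplet dialect: genes x cells matrix.mtx, genes.tsv, barcodes.tsv,
    plus metadata.tsv with the per-cell annotation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X
    sio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")
    return outdir


def read_10x_dir(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(sio.mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta = indir / "metadata.tsv"
    if meta.exists():
        obs = pd.read_csv(meta, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
        obs = obs.loc[cells]
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = genes
    return adata


def write_dense_tsv(adata: ad.AnnData, path) -> None:
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).to_csv(path, sep="\t")


def read_dense_tsv(path, obs: pd.DataFrame | None = None) -> ad.AnnData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    adata = ad.AnnData(X=df.to_numpy(), obs=obs if obs is not None
                       else pd.DataFrame(index=df.index))
    adata.obs_names = df.index.astype(str)
    adata.var_names = df.columns.astype(str)
    return adata


def read_tcr_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "locus": str, "cdr3": str})
    required = {"cell_id", "locus", "productive", "cdr3"}
    if not required <= set(df.columns):
        raise ValueError(f"TCR table needs columns {sorted(required)}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
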