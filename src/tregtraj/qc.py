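"""Cell-level quality control, TCR-rule filtering, log-normalization and
variable-gene selection.

QC follows standard droplet-data conventions for this assay: cells
are kept when their total UMI count lies in [1000, 15000] and their number
of detected genes (>=1 UMI) in [700, 3500], both bounds inclusive.
Mitochondrial content is deliberately not filtered on.

TCR-based rules consume a reconstructed-chain table (one row per chain:
cell id, locus in {A, B, G, D}, productive flag, CDR3):

* ``no_tcr``   — no chain detected at all; removed for stringency.
* ``doublet``  — more than two distinct recombinants on one locus.  Even
  without allelic exclusion a single cell can carry at most two recombined
  alleles per locus, so a third recombinant implies a cell doublet.  A
  recombinant is a distinct (locus, CDR3) pair; unproductive chains count.
* ``gd``       — at least one gamma and one delta chain and no alpha-beta
  pair (gamma-delta T cells, removed from the alpha-beta Treg analysis).
* ``ab``       — everything else (kept).

Reasons are assigned in the fixed order: low_umi, high_umi, low_genes,
high_genes, no_tcr, tcr_doublet, gd_tcell, pass.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "filter_by_counts",
    "classify_tcr_cells",
    "qc_report",
    "apply_qc",
    "log_normalize",
    "select_variable_genes",
]

QC_REASONS = (
    "low_umi", "high_umi", "low_genes", "high_genes",
    "no_tcr", "tcr_doublet", "gd_tcell", "pass",
)

VALID_LOCI = frozenset("ABGD")


def _counts_array(adata: ad.AnnData):
    X = adata.X
    return X if sp.issparse(X) else np.asarray(X)


def _per_cell_totals(X):
    if sp.issparse(X):
        umi = np.asarray(X.sum(axis=1)).ravel()
        genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        umi = X.sum(axis=1)
        genes = (X > 0).sum(axis=1)
    return umi, genes


def filter_by_counts(adata: ad.AnnData, umi_min: float = 1000, umi_max: float = 15000,
                     genes_min: float = 700, genes_max: float = 3500):
    """Keep cells with umi_min <= UMI <= umi_max and genes_min <= detected
    genes <= genes_max (inclusive bounds).  Returns (filtered, report)."""
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    if not (0 < umi_min < umi_max and 0 < genes_min < genes_max):
        raise ValueError("thresholds must be positive with min < max")
    umi, genes = _per_cell_totals(_counts_array(adata))
    reason = np.full(adata.n_obs, "pass", dtype=object)
    reason[genes > genes_max] = "high_genes"
    reason[genes < genes_min] = "low_genes"
    reason[umi > umi_max] = "high_umi"
    reason[umi < umi_min] = "low_umi"
    report = pd.DataFrame(
        {"n_umi": umi, "n_genes": genes, "reason": reason, "pass": reason == "pass"},
        index=adata.obs_names,
    )
    kept = adata[report["pass"].to_numpy()].copy()
    if kept.n_obs == 0:
        warnings.warn("all cells removed by count filters")
    return kept, report


def classify_tcr_cells(tcr: pd.DataFrame, cells) -> pd.Series:
    """Assign each cell to {no_tcr, doublet, gd, ab} from its TCR chains.

    Precedence: no_tcr > doublet > gd > ab.
    """
    bad = set(tcr["locus"]) - VALID_LOCI
    if bad:
        raise ValueError(f"unknown TCR locus code(s): {sorted(bad)}")
    cells = pd.Index(cells)
    # distinct recombinants per (cell, locus): unique (locus, CDR3) pairs
    uniq = tcr.drop_duplicates(["cell_id", "locus", "cdr3"])
    per_locus = uniq.groupby(["cell_id", "locus"], sort=False).size().unstack(fill_value=0)
    per_locus = per_locus.reindex(index=cells, columns=["A", "B", "G", "D"], fill_value=0)

    has = per_locus > 0
    out = np.full(len(cells), "ab", dtype=object)
    is_gd = has["G"] & has["D"] & ~(has["A"] & has["B"])
    out[is_gd.to_numpy()] = "gd"
    is_doublet = (per_locus > 2).any(axis=1)
    out[is_doublet.to_numpy()] = "doublet"
    no_tcr = per_locus.sum(axis=1) == 0
    out[no_tcr.to_numpy()] = "no_tcr"
    return pd.Series(out, index=cells, name="tcr_class")


def qc_report(adata: ad.AnnData, tcr: pd.DataFrame | None = None,
              umi_min: float = 1000, umi_max: float = 15000,
              genes_min: float = 700, genes_max: float = 3500) -> pd.DataFrame:
    """Per-cell pass/fail with exactly one reason, applied in the documented
    fixed order (count filters first, then TCR rules)."""
    _, counts_rep = filter_by_counts(adata, umi_min, umi_max, genes_min, genes_max)
    reason = counts_rep["reason"].to_numpy(dtype=object).copy()
    if tcr is not None:
        tcr_class = classify_tcr_cells(tcr, adata.obs_names)
        remap = {"no_tcr": "no_tcr", "doublet": "tcr_doublet", "gd": "gd_tcell"}
        for cls, why in remap.items():
            hit = (tcr_class == cls).to_numpy() & (reason == "pass")
            reason[hit] = why
    report = counts_rep.copy()
    report["reason"] = reason
    report["pass"] = reason == "pass"
    return report


def apply_qc(adata: ad.AnnData, report: pd.DataFrame) -> ad.AnnData:
    """Subset a dataset to the QC-passing cells of a report."""
    keep = report.loc[adata.obs_names, "pass"].to_numpy()
    return adata[keep].copy()


def log_normalize(adata_or_matrix, scale: float = 10_000.0):
    """x_cg = ln(1 + scale * count_cg / total_c); zero counts map to zero.

    Accepts an AnnData (returns a copy with normalized ``.X`` and counts
    kept in ``.layers["counts"]``) or a bare matrix (returns an ndarray).
    """
    if isinstance(adata_or_matrix, ad.AnnData):
        X = _counts_array(adata_or_matrix)
    else:
        X = adata_or_matrix
        X = X if sp.issparse(X) else np.asarray(X)
    totals = (np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else X.sum(axis=1))
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be filtered before normalization")
    if sp.issparse(X):
        norm = X.tocsr().astype(float)
        inv = scale / totals
        norm = sp.diags(inv) @ norm
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(scale * X / totals[:, None])
    if isinstance(adata_or_matrix, ad.AnnData):
        out = adata_or_matrix.copy()
        out.layers["counts"] = out.X
        out.X = norm
        return out
    return norm


def select_variable_genes(norm, gene_ids=None, n_bins: int = 100, n_top: int = 500,
                          robust: bool = True):
    """Highly variable genes by binned dispersion z-score.

    Mean and dispersion follow the droplet-toolkit convention and are
    computed on the de-logged scale: for normalized values x,
    mean = ln(mean(e^x - 1) + 1) and dispersion = ln of the variance/mean
    ratio of e^x - 1 (the log-normalized scale would compress precisely
    the biological variance being sought).  Genes are placed into
    ``n_bins`` equal-frequency bins of mean expression, the dispersion
    z-score is computed within each bin, and the top ``n_top`` genes by z
    are returned (ties broken deterministically by gene id).

    By default the within-bin z-score is robust (median/MAD): truly
    variable genes inflate their own bin's mean and standard deviation,
    which suppresses exactly the genes being sought whenever several land
    in one bin; the robust location/scale is insensitive to them.
    ``robust=False`` gives the plain mean/sd z-score.
    """
    if isinstance(norm, ad.AnnData):
        gene_ids = norm.var_names if gene_ids is None else gene_ids
        X = norm.X
    else:
        X = norm
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    gene_ids = pd.Index(gene_ids if gene_ids is not None else range(X.shape[1])).astype(str)
    E = np.expm1(X)
    mean_raw = E.mean(axis=0)
    var_raw = E.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    mean = np.log1p(mean_raw)
    nonzero = mean_raw > 0
    if int(nonzero.sum()) < n_bins:
        raise ValueError(f"need >= {n_bins} genes with nonzero mean")
    if n_top > X.shape[1]:
        raise ValueError("n_top exceeds the number of genes")

    with np.errstate(divide="ignore", invalid="ignore"):
        vmr = np.where(nonzero, var_raw / np.where(nonzero, mean_raw, 1.0), 0.0)
        disp = np.where(vmr > 0, np.log(np.where(vmr > 0, vmr, 1.0)), -np.inf)
    disp[~np.isfinite(disp)] = np.nan

    # equal-frequency bins over genes with nonzero mean; deterministic via
    # stable mean-then-id ordering
    order = np.lexsort((gene_ids[nonzero], mean[nonzero]))
    idx_nonzero = np.flatnonzero(nonzero)[order]
    bins = np.array_split(idx_nonzero, n_bins)
    z = np.zeros(X.shape[1])
    for members in bins:
        d = disp[members]
        ok = np.isfinite(d)
        if ok.sum() < 2:
            continue
        if robust:
            med = np.median(d[ok])
            scale = np.median(np.abs(d[ok] - med)) * 1.4826
            if scale > 0:
                z[members[ok]] = (d[ok] - med) / scale
        else:
            sd = d[ok].std(ddof=0)
            if sd > 0:
                z[members[ok]] = (d[ok] - d[ok].mean()) / sd
    rank = np.lexsort((gene_ids, -z))
    return list(gene_ids[rank[:n_top]])
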