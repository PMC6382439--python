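"""Differential expression and signature scoring.

One-vs-rest and pairwise marker detection with the conventions of the
reference droplet toolkit: a two-sided Wilcoxon rank-sum test (tie-corrected
normal approximation) on log-normalized values, Bonferroni correction over
the genes actually tested in each contrast, and the fold-change convention

    avg_logFC = ln(mean(e^x - 1) + 1)_A  -  ln(mean(e^x - 1) + 1)_B

i.e. natural log of de-logged group means plus one.  A gene is tested only
if it is expressed (value > 0) in at least ``min_frac`` of either group
(default 5%; a 1% fallback applies to whole-dataset cross-tissue
comparisons).  A gene is reported as significant when |avg_logFC| >= 0.25
and Bonferroni-adjusted p <= 0.05.

The two-pass union scheme re-tests each contrast of a family on the union
of all contrasts' tested-gene sets so p-values are comparable across
contrasts.  The NLT/LT signature score of a cluster is the ratio of NLT- to
LT-signature genes among its significantly upregulated markers, with the
denominator floored at one.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

__all__ = [
    "wilcoxon_de",
    "two_pass_union_de",
    "find_all_markers",
    "nlt_lt_score",
]


def _dense(X):
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def _resolve(matrix, gene_ids):
    if isinstance(matrix, ad.AnnData):
        return _dense(matrix.X), pd.Index(matrix.var_names)
    return _dense(matrix), pd.Index(gene_ids)


def wilcoxon_de(matrix, group_a, group_b, gene_ids=None, min_frac: float = 0.05,
                logfc_min: float = 0.25, alpha: float = 0.05,
                tested_genes=None) -> pd.DataFrame:
    """Two-group Wilcoxon differential expression on normalized values.

    ``group_a``/``group_b`` are disjoint boolean masks or index arrays over
    cells.  ``tested_genes`` overrides the min_frac expression filter (used
    by the two-pass union scheme).  Returns one row per tested gene with
    columns gene, avg_logFC, pct_in, pct_out, p_raw, p_adj, significant.
    """
    X, genes = _resolve(matrix, gene_ids)
    a = np.zeros(X.shape[0], bool); a[np.asarray(group_a)] = True
    b = np.zeros(X.shape[0], bool); b[np.asarray(group_b)] = True
    if not a.any() or not b.any():
        raise ValueError("both groups must be non-empty")
    if (a & b).any():
        raise ValueError("groups overlap")

    Xa, Xb = X[a], X[b]
    frac_a = (Xa > 0).mean(axis=0)
    frac_b = (Xb > 0).mean(axis=0)
    if tested_genes is not None:
        test_mask = genes.isin(pd.Index(tested_genes))
    else:
        test_mask = (frac_a >= min_frac) | (frac_b >= min_frac)
    cols = np.flatnonzero(test_mask)
    if cols.size == 0:
        return pd.DataFrame(
            columns=["gene", "avg_logFC", "pct_in", "pct_out", "p_raw", "p_adj", "significant"]
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-tied genes raise a harmless warning
        p_raw = mannwhitneyu(Xa[:, cols], Xb[:, cols], alternative="two-sided",
                             method="asymptotic", axis=0).pvalue
    p_raw = np.nan_to_num(p_raw, nan=1.0)
    logfc = (np.log(np.expm1(Xa[:, cols]).mean(axis=0) + 1.0)
             - np.log(np.expm1(Xb[:, cols]).mean(axis=0) + 1.0))
    n_tested = cols.size
    p_adj = np.minimum(p_raw * n_tested, 1.0)
    out = pd.DataFrame(
        {
            "gene": genes[cols],
            "avg_logFC": logfc,
            "pct_in": frac_a[cols],
            "pct_out": frac_b[cols],
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    out["significant"] = (out["avg_logFC"].abs() >= logfc_min) & (out["p_adj"] <= alpha)
    return out.set_index("gene", drop=False)


def two_pass_union_de(matrix, contrasts, gene_ids=None, min_frac: float = 0.05,
                      **kwargs) -> pd.DataFrame:
    """Run a family of contrasts twice: pass one determines each contrast's
    expressed-gene set, pass two re-tests every contrast on the union of
    those sets (min_frac waived for union members).

    ``contrasts`` is a list of ``(name, group_a, group_b)``.  Returns the
    concatenated marker table with a ``contrast`` column.
    """
    if len(contrasts) < 2:
        if len(contrasts) == 1:
            name, a, b = contrasts[0]
            t = wilcoxon_de(matrix, a, b, gene_ids=gene_ids, min_frac=min_frac, **kwargs)
            t.insert(0, "contrast", name)
            return t
        raise ValueError("need at least one contrast")
    union: set = set()
    for name, a, b in contrasts:
        t = wilcoxon_de(matrix, a, b, gene_ids=gene_ids, min_frac=min_frac, **kwargs)
        union.update(t["gene"])
    parts = []
    for name, a, b in contrasts:
        t = wilcoxon_de(matrix, a, b, gene_ids=gene_ids, tested_genes=sorted(union), **kwargs)
        t.insert(0, "contrast", name)
        parts.append(t)
    return pd.concat(parts, axis=0)


def find_all_markers(matrix, clusters, gene_ids=None, **kwargs) -> pd.DataFrame:
    """One-vs-rest marker detection per cluster (upregulated = avg_logFC > 0)."""
    clusters = pd.Series(np.asarray(clusters))
    if clusters.nunique() < 2:
        raise ValueError("need at least two clusters")
    parts = []
    for name, idx in clusters.groupby(clusters).groups.items():
        mask = clusters.index.isin(idx)
        if mask.sum() < 2:
            warnings.warn(f"cluster {name!r} has fewer than 2 cells; skipped")
            continue
        t = wilcoxon_de(matrix, mask, ~mask, gene_ids=gene_ids, **kwargs)
        t.insert(0, "cluster", name)
        t["upregulated"] = t["avg_logFC"] > 0
        parts.append(t)
    return pd.concat(parts, axis=0) if parts else pd.DataFrame()


def nlt_lt_score(markers: pd.DataFrame, nlt_genes, lt_genes) -> pd.DataFrame:
    """Per-cluster NLT/LT signature score.

    Over each cluster's significant upregulated markers, counts the members
    of the NLT and LT signature sets and reports
    ``score = n_nlt_up / max(n_lt_up, 1)`` (denominator floored at one so a
    cluster with zero LT hits still gets a finite score; both raw counts are
    reported so alternatives can be recomputed).
    """
    nlt, lt = set(nlt_genes), set(lt_genes)
    if not nlt or not lt:
        raise ValueError("signature sets must be non-empty")
    if nlt & lt:
        raise ValueError("signature sets must be disjoint")
    rows = []
    for cluster, t in markers.groupby("cluster"):
        up = set(t.loc[t["significant"] & (t["avg_logFC"] > 0), "gene"])
        n_nlt, n_lt = len(up & nlt), len(up & lt)
        score = 0.0 if (n_nlt == 0 and n_lt == 0) else n_nlt / max(n_lt, 1)
        rows.append((cluster, n_nlt, n_lt, score))
    return pd.DataFrame(rows, columns=["cluster", "n_nlt_up", "n_lt_up", "score"]).set_index("cluster")
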