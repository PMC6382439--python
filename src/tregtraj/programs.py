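"""Gene-program temporal ordering along the adaptation trajectory.

Switch-gene kinetics are summarised at the gene-set level: for each term of
a GMT collection enriched among the switch genes (plain one-sided
hypergeometric test, BH-corrected), the mean activation/deactivation point
``mean_t0`` over the term's switch-reported members gives the program's
position in the cascade.  Terms with fewer than two switch members are
dropped.  Orderings from two trajectories are compared by Spearman
correlation over the shared terms' mean_t0 (exact permutation p-value for
up to 10 shared terms), and per-gene t0 values from two conditions are
compared with a Welch t test plus Spearman correlation.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata, spearmanr, ttest_ind, ttest_rel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
    "term_activation_times",
    "compare_orderings",
    "compare_condition_t0",
]


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def hypergeometric_enrichment(switch_genes, background_genes, gene_sets: dict,
                              q_max: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each gene set among the switch
    genes, relative to the background universe; BH-adjusted."""
    background = set(background_genes)
    if not background:
        raise ValueError("background gene universe is empty")
    switch = set(switch_genes) & background
    if set(switch_genes) - background:
        raise ValueError("switch genes must be a subset of the background")
    N, n = len(background), len(switch)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & switch)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, p))
    df = pd.DataFrame(rows, columns=["term", "n_hits", "set_size", "p_raw"])
    if len(df):
        df["q"] = multipletests(df["p_raw"], method="fdr_bh")[1]
        df["enriched"] = df["q"] <= q_max
        df = df.sort_values(["p_raw", "term"]).set_index("term", drop=False)
    return df


def term_activation_times(switch_table: pd.DataFrame, terms: dict,
                          min_genes: int = 2) -> pd.DataFrame:
    """Mean t0 per term over its switch-reported member genes.

    Terms with fewer than ``min_genes`` reported members are dropped.
    Per-direction means are also emitted alongside the overall mean.
    """
    rep = switch_table.loc[switch_table["reported"]] if "reported" in switch_table else switch_table
    t0 = rep.set_index("gene")["t0"]
    direction = rep.set_index("gene")["direction"] if "direction" in rep else None
    rows = []
    for name, members in terms.items():
        hit = [g for g in members if g in t0.index]
        if len(hit) < min_genes:
            continue
        vals = t0.loc[hit]
        row = {"term": name, "mean_t0": float(vals.mean()), "n_genes": len(hit)}
        if direction is not None:
            d = direction.loc[hit]
            row["dominant_direction"] = d.mode().iloc[0]
            for which in ("activation", "inhibition"):
                sel = vals[d == which]
                row[f"mean_t0_{which}"] = float(sel.mean()) if len(sel) else float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("term", drop=False) if len(df) else df


def _exact_spearman_p(x, y) -> float:
    """Two-sided exact permutation p-value of Spearman's rho (small n)."""
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    rxc = rx - rx.mean()
    rx_norm = float(np.sqrt((rxc**2).sum()))
    count = total = 0
    chunk = []

    def flush(chunk):
        arr = np.asarray(chunk, float)
        c = arr - arr.mean(axis=1, keepdims=True)
        rhos = (c @ rxc) / (np.sqrt((c**2).sum(axis=1)) * rx_norm)
        return int((np.abs(rhos) >= obs - 1e-12).sum()), len(arr)

    for perm in permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            c, tot = flush(chunk)
            count += c
            total += tot
            chunk = []
    if chunk:
        c, tot = flush(chunk)
        count += c
        total += tot
    return count / total


def compare_orderings(timing_a: pd.DataFrame, timing_b: pd.DataFrame) -> dict:
    """Spearman correlation between two trajectories' program orderings.

    Computed over the mean_t0 of terms present in both; exact permutation
    p for <= 10 shared terms, asymptotic otherwise.
    """
    shared = sorted(set(timing_a["term"]) & set(timing_b["term"]))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared terms")
    a = timing_a.set_index("term").loc[shared, "mean_t0"].to_numpy()
    b = timing_b.set_index("term").loc[shared, "mean_t0"].to_numpy()
    rho, p_asym = spearmanr(a, b)
    if len(shared) <= 10:
        p = _exact_spearman_p(a, b)
    else:
        p = float(p_asym)
    return {"rho": float(rho), "p": p, "n_terms": len(shared), "terms": shared}


def compare_condition_t0(fits_a: pd.DataFrame, fits_b: pd.DataFrame,
                         categories: pd.Series | None = None) -> dict:
    """Compare activation points of genes shared between two conditions.

    Reports per-gene delta t0, a Welch two-sample t test (plus the paired
    variant, since gene pairing exists), Spearman correlation of the
    (t0_a, t0_b) pairs, group means +- SE, and per-category mean +- SE of
    delta t0 when a gene -> category mapping is supplied.
    """
    rep_a = fits_a.loc[fits_a["reported"]] if "reported" in fits_a else fits_a
    rep_b = fits_b.loc[fits_b["reported"]] if "reported" in fits_b else fits_b
    shared = sorted(set(rep_a["gene"]) & set(rep_b["gene"]))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    a = rep_a.set_index("gene").loc[shared, "t0"].to_numpy(float)
    b = rep_b.set_index("gene").loc[shared, "t0"].to_numpy(float)
    delta = pd.DataFrame({"gene": shared, "t0_a": a, "t0_b": b, "delta_t0": b - a}
                         ).set_index("gene", drop=False)
    if np.allclose(a, b):
        p_welch, p_paired = 1.0, 1.0
    else:
        p_welch = float(ttest_ind(a, b, equal_var=False).pvalue)
        p_paired = float(ttest_rel(a, b).pvalue)
        if math.isnan(p_welch):
            p_welch = 1.0
        if math.isnan(p_paired):
            p_paired = 1.0
    rho = float(spearmanr(a, b).statistic) if len(shared) > 1 else float("nan")
    out = {
        "delta": delta,
        "t_test_p": p_welch,
        "paired_t_test_p": p_paired,
        "spearman_rho": rho,
        "mean_a": float(a.mean()),
        "se_a": float(a.std(ddof=1) / np.sqrt(len(a))),
        "mean_b": float(b.mean()),
        "se_b": float(b.std(ddof=1) / np.sqrt(len(b))),
        "n_shared": len(shared),
    }
    if categories is not None:
        cats = pd.Series(categories)
        delta["category"] = cats.reindex(delta.index)
        grp = delta.groupby("category")["delta_t0"]
        out["per_category"] = pd.DataFrame(
            {"mean_delta_t0": grp.mean(), "se_delta_t0": grp.sem(), "n": grp.size()}
        )
    return out
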