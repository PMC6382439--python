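"""Switch-like gene kinetics along the adaptation coordinate.

Each gene's normalized expression along the pseudospace coordinate ``t``
is modelled as a sigmoid

    S(t) = 2 * mu0 / (1 + exp(-k * (t - t0)))

where ``mu0`` is the mean expression between the "on" and "off" states,
``t0`` the point at which the switch happens, and ``k`` the inclination —
the activation strength, whose sign gives the direction of the switch
(activation if k > 0, inhibition if k < 0).  Parameters maximise a
Gaussian likelihood with constant (profiled) variance; switch-like
behaviour is tested by a likelihood-ratio test against the constant-mean
model with two degrees of freedom, followed by Benjamini-Hochberg
correction over the tested genes.

Gene filters keep the fits to informative genes: a gene is fitted only when it
is expressed in at least 30 cells and its absolute Pearson correlation
with the coordinate exceeds 0.25; a fit is reported when q <= 0.05 and t0
lies within the coordinate's range.  For unbalanced subpopulations the
subsample-median scheme refits on repeated subsamples matching the
smallest subpopulation size and takes element-wise medians of the
parameters over rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "sigmoid",
    "SwitchFit",
    "fit_switch_gene",
    "fit_all_switch_genes",
    "subsample_median_fit",
    "shared_switch_genes",
]


def sigmoid(t, mu0, k, t0):
    """S(t) = 2*mu0 / (1 + e^(-k (t - t0))), numerically safe for large |k|."""
    return 2.0 * mu0 * expit(np.asarray(k, float) * (np.asarray(t, float) - t0))


@dataclass
class SwitchFit:
    """Maximum-likelihood sigmoid fit for one gene."""

    gene: str
    mu0: float
    k: float
    t0: float
    loglik_sigmoid: float
    loglik_constant: float
    p_raw: float
    q: float = float("nan")
    valid: bool = True

    @property
    def direction(self) -> str:
        return "activation" if self.k > 0 else "inhibition"


def _gauss_loglik(rss, n):
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def fit_switch_gene(expr, t, gene: str = "", k_bound_scale: float = 1e4) -> SwitchFit:
    """Fit the sigmoid to one gene by deterministic multi-start optimisation.

    Starts span t0 at the 20/50/80% quantiles of ``t`` and k at
    {+-1, +-10, +-100} / range(t) (the steep starts cover near-step
    switches), with mu0 at the mean expression; |k| is bounded
    by ``k_bound_scale / range(t)`` for numerical stability.  The constant
    model (k = 0) is nested in the sigmoid, so the sigmoid log likelihood
    never falls below the constant one.
    """
    y = np.asarray(expr, float)
    t = np.asarray(t, float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 cells")
    rng_t = float(t.max() - t.min())
    if rng_t == 0:
        raise ValueError("pseudospace coordinate is constant")

    ybar = float(y.mean())
    rss0 = float(((y - ybar) ** 2).sum())
    ll0 = _gauss_loglik(rss0, n)

    mu0_start = max(ybar, 1e-3)
    k_max = k_bound_scale / rng_t
    t0_starts = np.quantile(t, [0.2, 0.5, 0.8])
    k_starts = np.array([1.0, -1.0, 10.0, -10.0, 100.0, -100.0]) / rng_t
    lo = np.array([1e-8, -k_max, t.min() - rng_t])
    hi = np.array([np.inf, k_max, t.max() + rng_t])

    def resid(p):
        return sigmoid(t, p[0], p[1], p[2]) - y

    def jac(p):
        mu0, k, t0 = p
        s = expit(k * (t - t0))
        ds = s * (1.0 - s)
        return np.column_stack([2.0 * s, 2.0 * mu0 * ds * (t - t0), -2.0 * mu0 * ds * k])

    best, best_rss = None, np.inf
    for t0s in t0_starts:
        for ks in k_starts:
            p0 = np.clip([mu0_start, ks, t0s], lo, hi)
            try:
                res = least_squares(resid, p0, jac=jac, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            rss = float(2.0 * res.cost)
            if rss < best_rss:
                best, best_rss = res.x, rss
    if best is None or ybar <= 0:
        return SwitchFit(gene, float("nan"), 0.0, float("nan"), ll0, ll0, 1.0, valid=False)

    mu0, k, t0 = map(float, best)
    ll1 = _gauss_loglik(best_rss, n)
    if ll1 < ll0:  # constant model wins: report the boundary (k = 0) fit
        mu0, k, t0, ll1 = mu0_start, 0.0, float(np.median(t)), ll0
        best_rss = rss0
    stat = max(2.0 * (ll1 - ll0), 0.0)
    p = float(chi2.sf(stat, df=2))
    return SwitchFit(gene, mu0, k, t0, ll1, ll0, p)


def _expr_matrix(matrix, gene_ids):
    if isinstance(matrix, ad.AnnData):
        X = matrix.X
        gene_ids = list(matrix.var_names) if gene_ids is None else list(gene_ids)
    else:
        X = matrix
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
    if gene_ids is None:
        gene_ids = [str(j) for j in range(X.shape[1])]
    return X, list(gene_ids)


def fit_all_switch_genes(matrix, lv, gene_ids=None, min_cells: int = 30,
                         min_abs_corr: float = 0.25, q_max: float = 0.05,
                         exclude_genes=None) -> pd.DataFrame:
    """Sigmoid fits for every gene passing the pre-filters.

    Pre-filters: expressed (value > 0) in >= ``min_cells`` cells AND
    |Pearson r| with the coordinate > ``min_abs_corr``; genes in
    ``exclude_genes`` are skipped.  BH q-values are computed over the
    fitted genes; ``reported`` flags fits with q <= q_max and t0 within
    [min(lv), max(lv)].
    """
    X, genes = _expr_matrix(matrix, gene_ids)
    lv = np.asarray(lv, float)
    n_cells_expr = (X > 0).sum(axis=0)
    lvc = lv - lv.mean()
    sd_lv = lv.std()
    sd_g = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ((X - X.mean(axis=0)) * lvc[:, None]).mean(axis=0) / np.where(
            sd_g == 0, np.inf, sd_g * sd_lv)
    excl = set(exclude_genes) if exclude_genes is not None else set()
    keep = (
        (n_cells_expr >= min_cells)
        & (np.abs(r) > min_abs_corr)
        & ~np.isin(genes, list(excl))
    )
    cols = np.flatnonzero(keep)
    if cols.size == 0:
        warnings.warn("no genes pass the switch pre-filters")
        return pd.DataFrame(columns=["gene", "mu0", "k", "t0", "loglik_sigmoid",
                                     "loglik_constant", "p_raw", "q", "direction",
                                     "lv_corr", "reported"])
    fits = [fit_switch_gene(X[:, j], lv, gene=genes[j]) for j in cols]
    df = pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "mu0": [f.mu0 for f in fits],
            "k": [f.k for f in fits],
            "t0": [f.t0 for f in fits],
            "loglik_sigmoid": [f.loglik_sigmoid for f in fits],
            "loglik_constant": [f.loglik_constant for f in fits],
            "p_raw": [f.p_raw for f in fits],
            "valid": [f.valid for f in fits],
            "lv_corr": r[cols],
        }
    ).set_index("gene", drop=False)
    valid = df["valid"].to_numpy()
    q = np.full(len(df), np.nan)
    if valid.any():
        q[valid] = multipletests(df.loc[valid, "p_raw"], method="fdr_bh")[1]
    df["q"] = q
    df["direction"] = np.where(df["k"] > 0, "activation", "inhibition")
    in_range = (df["t0"] >= lv.min()) & (df["t0"] <= lv.max())
    df["reported"] = valid & (df["q"] <= q_max) & in_range
    return df


def _balanced_subsample(groups: pd.Series, m: int, rng: np.random.Generator) -> np.ndarray:
    """One subsample round: m cells from every subpopulation, no replacement."""
    return np.concatenate([
        rng.choice(np.flatnonzero((groups == g).to_numpy()), size=m, replace=False)
        for g in groups.unique()
    ])


def subsample_median_fit(matrix, lv, groups, gene_ids=None, n_rounds: int = 100,
                         seed: int = 0, min_cells: int = 30,
                         min_abs_corr: float = 0.25, q_max: float = 0.05,
                         **kwargs) -> pd.DataFrame:
    """Median sigmoid parameters over repeated balanced subsamples.

    Each round draws, without replacement, ``min(group sizes)`` cells from
    every subpopulation, refits, and the per-gene parameters are the
    element-wise medians over the rounds in which the gene was fitted.  A
    gene is reported when it passes the filters (q and t0-range) in more
    than half of the rounds.
    """
    X, genes = _expr_matrix(matrix, gene_ids)
    lv = np.asarray(lv, float)
    groups = pd.Series(np.asarray(groups))
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two subpopulations")
    m = int(sizes.min())
    if m < 10:
        raise ValueError("smallest subpopulation must have >= 10 cells")
    rng = np.random.default_rng(seed)
    per_round = []
    for _ in range(n_rounds):
        idx = _balanced_subsample(groups, m, rng)
        fit = fit_all_switch_genes(X[idx], lv[idx], gene_ids=genes,
                                   min_cells=min_cells, min_abs_corr=min_abs_corr,
                                   q_max=q_max, **kwargs)
        per_round.append(fit)
    all_genes = sorted(set().union(*[set(f.index) for f in per_round]))
    rows = []
    for g in all_genes:
        sub = [f.loc[g] for f in per_round if g in f.index and bool(f.loc[g, "valid"])]
        if not sub:
            continue
        reported = sum(bool(s["reported"]) for s in sub)
        rows.append(
            {
                "gene": g,
                "mu0": float(np.median([s["mu0"] for s in sub])),
                "k": float(np.median([s["k"] for s in sub])),
                "t0": float(np.median([s["t0"] for s in sub])),
                "q": float(np.median([s["q"] for s in sub])),
                "n_rounds_fitted": len(sub),
                "n_rounds_passed": reported,
                "reported": reported > n_rounds / 2,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["direction"] = np.where(out["k"] > 0, "activation", "inhibition")
        out = out.set_index("gene", drop=False)
    return out


def shared_switch_genes(table_a: pd.DataFrame, table_b: pd.DataFrame):
    """Intersection of two reported switch-gene sets.

    Returns a dict with per-table counts, the shared genes and their
    (t0_a, t0_b) pairs.
    """
    rep_a = table_a.loc[table_a["reported"]] if "reported" in table_a else table_a
    rep_b = table_b.loc[table_b["reported"]] if "reported" in table_b else table_b
    shared = sorted(set(rep_a["gene"]) & set(rep_b["gene"]))
    pairs = pd.DataFrame(
        {
            "gene": shared,
            "t0_a": rep_a.set_index("gene").loc[shared, "t0"].to_numpy() if shared else [],
            "t0_b": rep_b.set_index("gene").loc[shared, "t0"].to_numpy() if shared else [],
        }
    ).set_index("gene", drop=False)
    return {
        "n_a": int(len(rep_a)),
        "n_b": int(len(rep_b)),
        "n_shared": len(shared),
        "shared": shared,
        "t0_pairs": pairs,
    }
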