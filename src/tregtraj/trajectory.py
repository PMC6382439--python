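"""Pseudospace inference: GPLVM with automatic relevance determination.

A Gaussian process latent variable model (GPLVM) places each cell at a
latent coordinate ``x_i`` in R^Q and models every (standardized) gene as an
independent GP over the latent space with an ARD exponentiated-quadratic
kernel

    k(x, x') = sigma_f^2 exp(-1/2 sum_q alpha_q (x_q - x'_q)^2) + sigma_n^2 delta

The per-dimension weights ``alpha_q`` (inverse squared lengthscales) are
the ARD relevances: dimensions the data does not need get alpha ~ 0.  The
model is fitted by MAP: latent points and kernel hyperparameters jointly
maximise the GP marginal likelihood plus a unit Gaussian prior on X, from a
PCA initialisation, with L-BFGS.  Only the *ordering* of cells along the
selected dimension is the contract — latent scale and sign are not
identifiable — so the adaptation dimension is chosen as the most relevant
dimension whose ordering correlates with tissue identity (point-biserial
r against the LT/NLT label) and oriented so the non-lymphoid pole is high.

The partitioned variant (manifold relevance determination, MRD) gives each
gene partition — cell-cycle genes, tissue marker genes, the rest — its own
kernel hyperparameters over *shared* latent coordinates, so per-partition
relevance profiles separate cell-cycle variation from tissue adaptation.
The adaptation dimension is then the one most relevant to the tissue-marker
partition among dimensions whose cell-cycle relevance share stays below a
documented fraction (twice the uniform share by default).

Held-out cells are projected by optimising, per cell, the trained model's
predictive likelihood over the new cell's latent position with all
hyperparameters frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize

__all__ = [
    "LatentEmbedding",
    "fit_gplvm",
    "fit_partitioned_gplvm",
    "project_cells",
    "lv_gene_correlation",
    "shared_proportion",
]

JITTER = 1e-6


def _as_array(Y):
    if isinstance(Y, ad.AnnData):
        Y = Y.X
    return np.asarray(Y.todense()) if sp.issparse(Y) else np.asarray(Y, float)


def _standardize(Y):
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0)
    if np.all(sd < 1e-12):
        raise ValueError("expression matrix is constant; nothing to embed")
    sd = np.where(sd < 1e-8, 1.0, sd)
    return (Y - mean) / sd, mean, sd


@dataclass
class LatentEmbedding:
    """Latent cell coordinates with ARD relevance and selection metadata."""

    X: np.ndarray                      # N x Q latent coordinates
    relevance: np.ndarray              # P x Q ARD weights (alpha), one row per partition
    partition_names: list
    hyperparams: list                  # per partition: dict(sf2, alpha, sn2)
    lv_index: int
    sign: float
    Y_std: list = field(repr=False, default_factory=list)   # per-partition standardized data
    scalers: list = field(repr=False, default_factory=list) # per-partition (mean, sd)
    gene_ids: list = field(default_factory=list)            # per-partition gene id lists
    trace: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def lv0(self) -> np.ndarray:
        """Oriented adaptation coordinate (LT pole low, NLT pole high)."""
        return self.sign * self.X[:, self.lv_index]

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        cols = {f"LV{q}": self.X[:, q] for q in range(self.X.shape[1])}
        df = pd.DataFrame(cols, index=cell_ids)
        df["lv0"] = self.lv0
        return df


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _pack(X, hypers):
    parts = [X.ravel()]
    for h in hypers:
        parts.append(np.concatenate([[h[0]], h[1], [h[2]]]))
    return np.concatenate(parts)


def _unpack(theta, N, Q, P):
    X = theta[: N * Q].reshape(N, Q)
    hypers, off = [], N * Q
    for _ in range(P):
        blk = theta[off: off + Q + 2]
        hypers.append((blk[0], blk[1:-1], blk[-1]))  # log sf2, log alpha, log sn2
        off += Q + 2
    return X, hypers


def _neg_objective(theta, Ss, Ds, N, Q):
    """Negative (penalised) GPLVM log likelihood and its gradient.

    ``Ss`` are the per-partition outer products Y Y^T; ``Ds`` the partition
    widths.  Returns (f, grad) for L-BFGS.
    """
    P = len(Ss)
    X, hypers = _unpack(theta, N, Q, P)
    d2 = np.empty((Q, N, N))
    for q in range(Q):
        diff = X[:, q, None] - X[None, :, q]
        d2[q] = diff * diff

    f = 0.5 * float((X * X).sum())
    gX = X.copy()
    ghypers = []
    for (lsf, lalpha, lsn), S, D in zip(hypers, Ss, Ds):
        sf2, alpha, sn2 = np.exp(lsf), np.exp(lalpha), np.exp(lsn)
        M = 0.5 * np.tensordot(alpha, d2, axes=(0, 0))
        Krbf = sf2 * np.exp(-M)
        K = Krbf + (sn2 + JITTER) * np.eye(N)
        L = cholesky(K, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        Kinv = cho_solve((L, True), np.eye(N))
        KinvS = Kinv @ S
        trKinvS = float((Kinv * S).sum())
        f += 0.5 * D * (N * np.log(2 * np.pi) + logdet) + 0.5 * trKinvS
        # dF/dK of the negative log likelihood: -1/2 (K^{-1} S K^{-1} - D K^{-1})
        G = -0.5 * (KinvS @ Kinv - D * Kinv)
        B = G * Krbf
        g_lsf = float(B.sum())
        g_lsn = float(np.trace(G)) * sn2
        g_lalpha = np.empty(Q)
        r = B.sum(axis=1)
        for q in range(Q):
            g_lalpha[q] = -0.5 * alpha[q] * float((B * d2[q]).sum())
            gX[:, q] += -2.0 * alpha[q] * (r * X[:, q] - B @ X[:, q])
        ghypers.append((g_lsf, g_lalpha, g_lsn))
    grad = _pack(gX, ghypers)
    return f, grad


def _pca_init(Y, Q, rng):
    Yc = Y - Y.mean(axis=0)
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    r = min(Q, s.size)
    X = np.zeros((Y.shape[0], Q))
    X[:, :r] = U[:, :r] * s[:r]
    sd0 = X[:, 0].std()
    if sd0 > 0:
        X /= sd0
    X += 0.01 * rng.standard_normal(X.shape)
    return X


def _fit_map(Y_parts, Q, seed, max_iter):
    N = Y_parts[0].shape[0]
    rng = np.random.default_rng(seed)
    X0 = _pca_init(np.hstack(Y_parts), Q, rng)
    sds = X0.std(axis=0)
    alpha0 = np.clip((sds / max(sds[0], 1e-8)) ** 2, 1e-3, 1.0)
    hypers0 = [(np.log(1.0), np.log(alpha0), np.log(0.5)) for _ in Y_parts]
    Ss = [Y @ Y.T for Y in Y_parts]
    Ds = [Y.shape[1] for Y in Y_parts]
    theta0 = _pack(X0, hypers0)
    res = minimize(_neg_objective, theta0, args=(Ss, Ds, N, Q), jac=True,
                   method="L-BFGS-B", options={"maxiter": max_iter, "maxfun": 2 * max_iter})
    if not res.success and "MAXLS" not in str(res.message):
        warnings.warn(f"GPLVM optimizer did not fully converge: {res.message}")
    X, hypers = _unpack(res.x, N, Q, len(Y_parts))
    var_x = X.var(axis=0)
    hdicts = [
        {
            "sf2": float(np.exp(l)),
            "alpha": np.exp(a),
            # ARD relevance: inverse squared lengthscale scaled by the
            # latent variance of the dimension, so a dimension the model
            # collapsed to zero (var -> 0 under the latent prior) reports
            # zero relevance regardless of its arbitrary raw alpha
            "relevance": np.exp(a) * var_x,
            "sn2": float(np.exp(n)),
        }
        for l, a, n in hypers
    ]
    trace = {"n_iter": int(res.nit), "neg_loglik": float(res.fun),
             "converged": bool(res.success), "message": str(res.message)}
    return X, hdicts, trace


# ---------------------------------------------------------------------------
# dimension selection
# ---------------------------------------------------------------------------

def _point_biserial(x, flag):
    flag = np.asarray(flag, bool)
    if flag.all() or not flag.any():
        return 0.0
    return float(np.corrcoef(x, flag.astype(float))[0, 1])


def _select_dimension(X, relevance_row, tissue_nlt, min_abs_r=0.3):
    order = np.argsort(relevance_row)[::-1]
    if tissue_nlt is None:
        return int(order[0]), 1.0
    rs = np.array([_point_biserial(X[:, q], tissue_nlt) for q in range(X.shape[1])])
    candidates = [q for q in order if abs(rs[q]) >= min_abs_r]
    lv = int(candidates[0]) if candidates else int(order[0])
    nlt = np.asarray(tissue_nlt, bool)
    sign = 1.0 if X[nlt, lv].mean() >= X[~nlt, lv].mean() else -1.0
    return lv, sign


def fit_gplvm(Y, q_latent: int = 6, seed: int = 0, tissue_nlt=None,
              gene_ids=None, max_iter: int = 1500) -> LatentEmbedding:
    """Fit the MAP GPLVM on log-normalized expression of variable genes.

    Genes are centred and unit-scaled before fitting.  If ``tissue_nlt``
    (boolean: cell is from the non-lymphoid tissue) is given, the
    adaptation dimension is selected and oriented; otherwise the most
    relevant dimension is taken with positive orientation.
    """
    if isinstance(Y, ad.AnnData) and gene_ids is None:
        gene_ids = list(Y.var_names)
    Yarr = _as_array(Y)
    if Yarr.shape[0] < 20:
        raise ValueError("need at least 20 cells to fit the GPLVM")
    Ystd, mean, sd = _standardize(Yarr)
    X, hdicts, trace = _fit_map([Ystd], q_latent, seed, max_iter)
    relevance = np.vstack([h["relevance"] for h in hdicts])
    lv, sign = _select_dimension(X, relevance[0], tissue_nlt)
    return LatentEmbedding(
        X=X, relevance=relevance, partition_names=["all"], hyperparams=hdicts,
        lv_index=lv, sign=sign, Y_std=[Ystd], scalers=[(mean, sd)],
        gene_ids=[list(gene_ids) if gene_ids is not None else None],
        trace=trace, seed=seed,
    )


def fit_partitioned_gplvm(partitions: dict, q_latent: int = 12, seed: int = 0,
                          tissue_nlt=None, cellcycle_max_share: float | None = None,
                          max_iter: int = 1500, gene_ids: dict | None = None):
    """Shared-latent GPLVM with per-partition ARD relevance (MRD).

    ``partitions`` maps the three section names — "cellcycle",
    "tissue_markers", "rest" — to cell x gene matrices over the same cells.
    Returns ``(embedding, partition_relevance)`` where the relevance table
    has one row per partition and one column per latent dimension.

    The adaptation dimension maximises the tissue-marker relevance share
    among dimensions whose cell-cycle relevance share is below
    ``cellcycle_max_share`` (default ``2/q_latent``, i.e. twice the uniform
    share); if no dimension qualifies the constraint is dropped.  With a
    cell-cycle partition of flat genes the share profile is near-uniform
    and the rule reduces to plain relevance.
    """
    names = list(partitions)
    if not partitions or any(
        _as_array(v).shape[1] == 0 for v in partitions.values()
    ):
        raise ValueError("every partition must contain at least one gene")
    arrays, scalers, gids = [], [], []
    for name in names:
        arr = _as_array(partitions[name])
        std, mean, sd = _standardize(arr)
        arrays.append(std)
        scalers.append((mean, sd))
        if gene_ids and name in gene_ids:
            gids.append(list(gene_ids[name]))
        elif isinstance(partitions[name], ad.AnnData):
            gids.append(list(partitions[name].var_names))
        else:
            gids.append(None)
    X, hdicts, trace = _fit_map(arrays, q_latent, seed, max_iter)
    relevance = np.vstack([h["relevance"] for h in hdicts])
    rel = pd.DataFrame(relevance, index=names, columns=[f"LV{q}" for q in range(q_latent)])

    share = relevance / relevance.sum(axis=1, keepdims=True)
    cc_share = share[names.index("cellcycle")] if "cellcycle" in names else np.zeros(q_latent)
    tissue_row = names.index("tissue_markers") if "tissue_markers" in names else 0
    t_share = share[tissue_row]
    cap = cellcycle_max_share if cellcycle_max_share is not None else 2.0 / q_latent
    ok = cc_share < cap
    if not ok.any():
        ok = np.ones(q_latent, bool)
    lv = int(np.flatnonzero(ok)[np.argmax(t_share[ok])])
    sign = 1.0
    if tissue_nlt is not None:
        nlt = np.asarray(tissue_nlt, bool)
        sign = 1.0 if X[nlt, lv].mean() >= X[~nlt, lv].mean() else -1.0
    emb = LatentEmbedding(
        X=X, relevance=relevance, partition_names=names, hyperparams=hdicts,
        lv_index=lv, sign=sign, Y_std=arrays, scalers=scalers, gene_ids=gids,
        trace=trace, seed=seed,
    )
    if "cellcycle" in names:
        emb.trace["cellcycle_lv"] = int(np.argmax(share[names.index("cellcycle")]))
    return emb, rel


# ---------------------------------------------------------------------------
# projection of held-out cells
# ---------------------------------------------------------------------------

def _align_genes(Ynew, new_ids, train_ids):
    """Reindex columns to the training gene space; missing genes zero-filled."""
    if train_ids is None or new_ids is None:
        return np.asarray(Ynew, float), 0
    pos = {g: i for i, g in enumerate(new_ids)}
    out = np.zeros((Ynew.shape[0], len(train_ids)))
    missing = 0
    for j, g in enumerate(train_ids):
        i = pos.get(g, -1)
        if i >= 0:
            out[:, j] = Ynew[:, i]
        else:
            missing += 1
    if missing == len(train_ids):
        raise ValueError("no gene overlap between query and model")
    if missing:
        warnings.warn(f"{missing} model genes absent from the query; zero-filled")
    return out, missing


def project_cells(embedding: LatentEmbedding, Y_new, gene_ids=None) -> np.ndarray:
    """Latent coordinates for new cells under the trained model.

    Each cell's position maximises the frozen model's GP predictive
    likelihood (plus the unit latent prior), initialised from the training
    cell with the most similar expression profile and from the origin.
    """
    if isinstance(Y_new, ad.AnnData) and gene_ids is None:
        gene_ids = list(Y_new.var_names)
    Yq = _as_array(Y_new)
    X = embedding.X
    N, Q = X.shape

    parts = []
    for p, name in enumerate(embedding.partition_names):
        mean, sd = embedding.scalers[p]
        aligned, _ = _align_genes(Yq, gene_ids, embedding.gene_ids[p])
        if aligned.shape[1] != mean.size:
            raise ValueError("query gene space does not match the model")
        Ystd_new = (aligned - mean) / sd
        h = embedding.hyperparams[p]
        d2 = sum((X[:, q, None] - X[None, :, q]) ** 2 * h["alpha"][q] for q in range(Q))
        K = h["sf2"] * np.exp(-0.5 * d2) + (h["sn2"] + JITTER) * np.eye(N)
        cf = cho_factor(K, lower=True)
        alphaY = cho_solve(cf, embedding.Y_std[p])
        parts.append((h, cf, alphaY, Ystd_new))

    def nll_grad(x, yrows):
        f = 0.5 * float(x @ x)
        g = x.copy()
        for (h, cf, alphaY, _), y in zip(parts, yrows):
            diff = x[None, :] - X            # N x Q
            k = h["sf2"] * np.exp(-0.5 * ((diff**2) * h["alpha"]).sum(axis=1))
            c = cho_solve(cf, k)
            v = max(h["sf2"] + h["sn2"] + JITTER - float(k @ c), 1e-9)
            mu = k @ alphaY
            resid = y - mu
            D = y.size
            f += 0.5 * (float(resid @ resid) / v + D * np.log(v) + D * np.log(2 * np.pi))
            Dk = -k[:, None] * diff * h["alpha"][None, :]   # N x Q
            w = alphaY @ resid
            beta = 0.5 * D / v - 0.5 * float(resid @ resid) / v**2
            g += -(w / v) @ Dk + beta * (-2.0 * (c @ Dk))
        return f, g

    # nearest training cell (standardized space, all partitions) for warm starts
    concat_train = np.hstack(embedding.Y_std)
    concat_new = np.hstack([p[3] for p in parts])
    out = np.empty((Yq.shape[0], Q))
    for i in range(Yq.shape[0]):
        d = ((concat_train - concat_new[i]) ** 2).sum(axis=1)
        starts = [X[int(np.argmin(d))], np.zeros(Q)]
        best, best_f = None, np.inf
        yrows = [p[3][i] for p in parts]
        for x0 in starts:
            res = minimize(nll_grad, x0, args=(yrows,), jac=True, method="L-BFGS-B",
                           options={"maxiter": 200})
            if res.fun < best_f:
                best, best_f = res.x, res.fun
        out[i] = best
    return out


# ---------------------------------------------------------------------------
# LV-gene correlation
# ---------------------------------------------------------------------------

def lv_gene_correlation(matrix, lv, gene_ids=None, min_abs_corr: float = 0.25) -> pd.DataFrame:
    """Pearson correlation of each gene with a latent coordinate; genes with
    |r| > min_abs_corr are flagged."""
    if isinstance(matrix, ad.AnnData) and gene_ids is None:
        gene_ids = list(matrix.var_names)
    X = _as_array(matrix)
    lv = np.asarray(lv, float)
    if lv.std() == 0:
        raise ValueError("latent coordinate has zero variance")
    lvc = (lv - lv.mean()) / lv.std()
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * lvc[:, None]).mean(axis=0) / np.where(sd == 0, np.inf, sd)
    out = pd.DataFrame(
        {"gene": gene_ids if gene_ids is not None else range(X.shape[1]), "r": r}
    ).set_index("gene", drop=False)
    out["flagged"] = out["r"].abs() > min_abs_corr
    return out


def shared_proportion(set_a, set_b) -> float:
    """Fraction of set_a's members also present in set_b (as a percentage)."""
    a, b = set(set_a), set(set_b)
    if not a:
        return float("nan")
    return 100.0 * len(a & b) / len(a)
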