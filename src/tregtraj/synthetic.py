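"""Synthetic single-cell datasets with planted ground truth.

Emulates the study design the pipeline targets: regulatory T cells
distributed along a one-dimensional lymphoid-to-non-lymphoid (LT->NLT)
adaptation coordinate spanning two tissues, with switch-like genes
(sigmoidal on/off kinetics with planted mu0, k, t0), flat genes,
per-subpopulation marker blocks, a cell-cycle program, negative-binomial
count noise with library-size variation, TCR chain tables (clean alpha-beta
cells, doublets, gamma-delta cells, TCR-less cells) and paired-species
marker tables with planted paralog swaps.

Two noise models are provided:

* ``noise="nb"`` draws unique-molecule counts from a negative binomial whose
  rate is calibrated so that the *expected log-normalized expression* of a
  gene equals its planted sigmoid value S(t).  Calibration is a numerical
  inversion on a grid; without it the discreteness/Jensen bias of
  ``ln(1 + scale * c / total)`` shifts the realised mean well below S(t).
* ``noise="gaussian"`` emits the normalized-scale matrix directly,
  ``x = S(t) + N(0, sd)`` — the idealised setting in which the sigmoid
  fitting stage is exactly specified.

All randomness flows through one ``numpy.random.Generator`` per call; the
same seed reproduces every output bit for bit.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import nbinom

__all__ = [
    "SimConfig",
    "generate_trajectory_dataset",
    "generate_from_truth",
    "generate_condition_pair",
    "generate_tcr_table",
    "generate_species_pair",
    "sigmoid_mean",
    "SpeciesPair",
]

#: scale factor of the downstream log-normalization the count model targets
NORM_SCALE = 10_000.0


def sigmoid_mean(t, mu0, k, t0):
    """Planted switch kinetics: S(t) = 2*mu0 / (1 + exp(-k*(t - t0)))."""
    return 2.0 * np.asarray(mu0) * expit(np.asarray(k) * (np.asarray(t) - np.asarray(t0)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted trajectory dataset.

    ``groups`` is an ordered list of ``(name, tissue, (t_lo, t_hi))``;
    consecutive windows overlap by default to emulate the continuous
    LT->NLT transition (cells of the lymphoid tissue reach into the
    non-lymphoid window and vice versa).
    """

    n_cells_per_group: int = 250
    groups: Sequence[tuple] = (
        ("LT-like", "mLN", (0.0, 0.6)),
        ("NLT-like", "colon", (0.4, 1.0)),
    )
    n_switch_genes: int = 60
    n_flat_genes: int = 60
    n_marker_genes_per_group: int = 20
    n_cellcycle_genes: int = 20
    n_background_genes: int = 1500
    nb_dispersion: float = 0.5
    library_size_log_mean: float = float(np.log(5000.0))
    library_size_log_sd: float = 0.25
    dropout_extra: float = 0.0
    seed: int = 0
    # noise model: "nb" (calibrated negative-binomial counts) or "gaussian"
    noise: str = "nb"
    gaussian_sd: float = 0.3
    # fraction of cells carrying the cell-cycle program
    cycling_fraction: float = 0.25
    # planted parameter ranges for switch genes
    mu0_range: tuple = (0.5, 1.5)
    k_range: tuple = (5.0, 15.0)
    t0_range: tuple = (0.1, 0.9)

    def validate(self) -> None:
        if self.n_cells_per_group <= 0 or not self.groups:
            raise ValueError("configuration yields zero cells")
        n_genes = (
            self.n_switch_genes
            + self.n_flat_genes
            + self.n_marker_genes_per_group * len(self.groups)
            + self.n_cellcycle_genes
            + self.n_background_genes
        )
        if n_genes <= 0:
            raise ValueError("configuration yields zero genes")
        for cnt in (
            self.n_switch_genes,
            self.n_flat_genes,
            self.n_marker_genes_per_group,
            self.n_cellcycle_genes,
            self.n_background_genes,
        ):
            if cnt < 0:
                raise ValueError("gene counts must be >= 0")
        for name, tissue, (lo, hi) in self.groups:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"t-window of group {name!r} must lie within [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.dropout_extra <= 1.0:
            raise ValueError("dropout_extra must be a probability")
        if self.noise not in ("nb", "gaussian"):
            raise ValueError("noise must be 'nb' or 'gaussian'")
        if not 0.0 <= self.cycling_fraction <= 1.0:
            raise ValueError("cycling_fraction must be a probability")


# ---------------------------------------------------------------------------
# gene truth construction
# ---------------------------------------------------------------------------

_MARKER_BASELINE = 0.05  # normalized-scale expression of a marker outside its owner group


def _make_gene_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_switch_genes):
        mu0 = rng.uniform(*config.mu0_range)
        k = rng.uniform(*config.k_range) * rng.choice([-1.0, 1.0])
        t0 = rng.uniform(*config.t0_range)
        rows.append((f"SW{i:04d}", "switch", mu0, k, t0, ""))
    for i in range(config.n_flat_genes):
        mu0 = rng.uniform(*config.mu0_range)
        rows.append((f"FL{i:04d}", "flat", mu0, 0.0, np.nan, ""))
    # In the two-group (LT vs NLT) design, tissue markers are graded along
    # the adaptation coordinate — steep sigmoids switching at the
    # window-overlap midpoint, rising toward the non-lymphoid pole for NLT
    # markers and falling for LT markers — mirroring markers that change
    # continuously across the transition.  With three or more groups
    # markers are flat blocks over their owner group's cells.
    n_groups = len(config.groups)
    graded = n_groups == 2
    overlap_mid = (0.5 * (config.groups[0][2][1] + config.groups[-1][2][0])
                   if graded else 0.5)
    for g, (name, _tissue, _win) in enumerate(config.groups):
        for i in range(config.n_marker_genes_per_group):
            mu0 = rng.uniform(1.0, 2.0)
            if graded and g == 1:
                k, t0 = rng.uniform(8.0, 16.0), overlap_mid
            elif graded and g == 0:
                k, t0 = -rng.uniform(8.0, 16.0), overlap_mid
            else:
                k, t0 = 0.0, np.nan
            rows.append((f"MK{g}{i:03d}", "marker", mu0, k, t0, name))
    for i in range(config.n_cellcycle_genes):
        mu0 = rng.uniform(1.0, 2.0)
        rows.append((f"CC{i:04d}", "cellcycle", mu0, 0.0, np.nan, ""))
    for i in range(config.n_background_genes):
        # housekeeping levels, log-normal across genes
        mu0 = float(min(np.exp(rng.normal(0.3, 0.7)), 4.0))
        rows.append((f"BG{i:04d}", "background", mu0, 0.0, np.nan, ""))
    truth = pd.DataFrame(rows, columns=["gene", "klass", "mu0", "k", "t0", "owner"])
    return truth.set_index("gene", drop=False)


def _mean_matrix(truth: pd.DataFrame, t: np.ndarray, group: np.ndarray,
                 cycling: np.ndarray) -> np.ndarray:
    """Target normalized-scale mean s_cg for every cell x gene."""
    n_cells, n_genes = t.size, len(truth)
    s = np.empty((n_cells, n_genes))
    klass = truth["klass"].to_numpy()
    mu0 = truth["mu0"].to_numpy()
    k = truth["k"].to_numpy()
    t0 = truth["t0"].to_numpy()
    owner = truth["owner"].to_numpy()

    sw = (klass == "switch") | ((klass == "marker") & (k != 0))
    s[:, sw] = sigmoid_mean(t[:, None], mu0[sw][None, :] / np.where(klass[sw] == "marker", 2.0, 1.0)[None, :],
                            k[sw][None, :], t0[sw][None, :])
    for j in np.flatnonzero(~sw):
        if klass[j] == "marker":
            col = np.full(n_cells, _MARKER_BASELINE)
            col[group == owner[j]] = mu0[j]
        elif klass[j] == "cellcycle":
            col = np.full(n_cells, _MARKER_BASELINE)
            col[cycling] = mu0[j]
        else:  # flat / background
            col = np.full(n_cells, mu0[j])
        s[:, j] = col
    return s


# ---------------------------------------------------------------------------
# calibrated negative-binomial count model
# ---------------------------------------------------------------------------

def _calibration_table(f: float, phi: float, s_max: float):
    """Tabulate E[ln(1 + f*c)] over a rate grid, c ~ NB(mean=mu, var=mu+phi*mu^2).

    Returns (expected_lognorm, mu_grid), both monotone increasing, for
    inverting a target normalized mean s into an NB rate mu.
    """
    mu_max = 4.0 * np.expm1(s_max) / f + 10.0
    mu_grid = np.concatenate([[0.0], np.geomspace(1e-6, mu_max, 400)])
    c_max = int(mu_max + 12.0 * np.sqrt(mu_max + phi * mu_max**2) + 20)
    c = np.arange(c_max + 1)
    r = 1.0 / phi
    p = r / (r + mu_grid[1:, None])
    pmf = nbinom.pmf(c[None, :], r, p)
    vals = pmf @ np.log1p(f * c)
    return np.concatenate([[0.0], vals]), mu_grid


def _draw_nb_counts(s: np.ndarray, bg_mask: np.ndarray, config: SimConfig,
                    rng: np.random.Generator):
    """Counts whose log-normalized expectation matches the planted means.

    Signal genes (switch/flat/marker/cellcycle) are calibrated exactly at
    the nominal depth; background genes fill the remaining library budget
    so that the expected total equals the nominal depth.  (Calibrating
    *every* gene is infeasible: per realized cell
    sum_g expm1(x_cg) == NORM_SCALE identically, while Jensen's inequality
    forces E[sum expm1(x)] above the planted sum — so the slack lands on
    the background compartment, whose planted levels are not analysed.)
    """
    depth = float(np.exp(config.library_size_log_mean))
    f = NORM_SCALE / depth
    sig = ~bg_mask
    mu = np.empty_like(s)
    exp_lognorm, mu_grid = _calibration_table(f, config.nb_dispersion,
                                              float(s[:, sig].max()) if sig.any() else 1.0)
    mu[:, sig] = np.interp(s[:, sig], exp_lognorm, mu_grid)
    if bg_mask.any():
        raw_bg = np.expm1(s[:, bg_mask]) / f
        budget = depth - float(mu[:, sig].sum(axis=1).mean())
        total_bg = float(raw_bg.sum(axis=1).mean())
        scale = budget / total_bg if budget > 0 and total_bg > 0 else 1.0
        mu[:, bg_mask] = raw_bg * scale

    # unit-mean relative library sizes (E[lib_rel] = 1) scaled to the depth
    sd = config.library_size_log_sd
    lib_rel = rng.lognormal(-0.5 * sd * sd, sd, s.shape[0])
    rate = lib_rel[:, None] * mu
    r = 1.0 / config.nb_dispersion
    p = r / (r + np.maximum(rate, 1e-12))
    counts = rng.negative_binomial(r, p)
    counts[rate <= 0] = 0
    if config.dropout_extra > 0:
        keep = rng.random(counts.shape) >= config.dropout_extra
        counts = counts * keep
    return counts.astype(np.int64)


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def generate_from_truth(config: SimConfig, truth: pd.DataFrame, seed: int,
                        condition: str = "control", cell_prefix: str = "cell"):
    """Draw a dataset from an existing planted gene-truth table.

    Used to emulate a second tissue pair or condition measured on the same
    underlying gene kinetics (e.g. cells to be projected onto a trajectory
    trained elsewhere).  Cells are drawn fresh from ``config.groups``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    names, tissues, t_list, cells = [], [], [], []
    for gi, (name, tissue, (lo, hi)) in enumerate(config.groups):
        n = config.n_cells_per_group
        t_list.append(rng.uniform(lo, hi, n))
        names += [name] * n
        tissues += [tissue] * n
        cells += [f"{cell_prefix}_{gi}_{i:05d}" for i in range(n)]
    t = np.concatenate(t_list)
    group = np.asarray(names)
    cycling = rng.random(t.size) < config.cycling_fraction

    s = _mean_matrix(truth, t, group, cycling)
    if config.noise == "nb":
        bg_mask = (truth["klass"] == "background").to_numpy()
        X = sp.csr_matrix(_draw_nb_counts(s, bg_mask, config, rng))
    else:
        X = s + rng.normal(0.0, config.gaussian_sd, s.shape)

    obs = pd.DataFrame(
        {
            "group": group,
            "tissue": tissues,
            "condition": condition,
            "cluster": group,
            "true_t": t,
            "cycling": cycling,
        },
        index=pd.Index(cells, name="cell_id"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=truth.drop(columns="gene"))
    adata.uns["noise"] = config.noise
    adata.uns["seed"] = seed
    return adata


def generate_trajectory_dataset(config: SimConfig):
    """Planted LT->NLT trajectory dataset.

    Returns ``(adata, truth)`` where ``adata`` holds counts (``noise="nb"``)
    or normalized values (``noise="gaussian"``) with per-cell metadata
    (``true_t``, ``group``, ``tissue``, ``cluster``, ``condition``,
    ``cycling``) in ``.obs``, and ``truth`` is the planted gene parameter
    table (also mirrored into ``adata.var``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _make_gene_truth(config, rng)
    adata = generate_from_truth(config, truth, seed=int(rng.integers(2**31 - 1)))
    adata.uns["seed"] = config.seed
    return adata, truth


def generate_condition_pair(config: SimConfig, shared_gene_fraction: float,
                            t0_jitter_sd: float, seed: int, t0_shift: float = 0.0):
    """Two trajectory datasets (e.g. control vs tumour) with partly shared
    switch genes whose activation points t0 differ by
    ``t0_shift + N(0, t0_jitter_sd)``.

    Genes switch-like in only one condition are flat in the other, so both
    datasets share one gene universe.  Returns
    ``((adata_a, truth_a), (adata_b, truth_b), shared)`` where ``shared``
    lists each shared switch gene with its t0 in both conditions.
    """
    if not 0.0 <= shared_gene_fraction <= 1.0:
        raise ValueError("shared_gene_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cfg_a = replace(config, seed=int(rng.integers(2**31 - 1)))
    adata_a, truth_a = generate_trajectory_dataset(cfg_a)

    sw = truth_a.index[truth_a["klass"] == "switch"]
    n_shared = int(round(shared_gene_fraction * len(sw)))
    shared_genes = list(sw[:n_shared])

    truth_b = truth_a.copy()
    # shared switch genes: jittered t0; others: flat in B
    jitter = rng.normal(0.0, t0_jitter_sd, n_shared) if t0_jitter_sd > 0 else np.zeros(n_shared)
    truth_b.loc[shared_genes, "t0"] = (
        truth_a.loc[shared_genes, "t0"].to_numpy() + t0_shift + jitter
    )
    dropped = sw[n_shared:]
    truth_b.loc[dropped, ["klass", "k", "t0"]] = ["flat", 0.0, np.nan]

    adata_b = generate_from_truth(config, truth_b, seed=int(rng.integers(2**31 - 1)),
                                  condition="perturbed", cell_prefix="cellB")

    shared = pd.DataFrame(
        {
            "gene": shared_genes,
            "t0_a": truth_a.loc[shared_genes, "t0"].to_numpy(),
            "t0_b": truth_b.loc[shared_genes, "t0"].to_numpy(),
        }
    ).set_index("gene", drop=False)
    shared["delta_t0"] = shared["t0_b"] - shared["t0_a"]
    return (adata_a, truth_a), (adata_b, truth_b), shared


# ---------------------------------------------------------------------------
# TCR tables
# ---------------------------------------------------------------------------

_CDR3_ALPHABET = np.array(list(string.ascii_uppercase))


def _random_cdr3(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 16))
    return "C" + "".join(rng.choice(_CDR3_ALPHABET, n)) + "F"


def generate_tcr_table(cell_ids, doublet_rate: float, gd_rate: float,
                       no_tcr_rate: float, seed: int):
    """Reconstructed-TCR chain table with planted QC categories.

    Clean alpha-beta cells get 1-2 productive A and 1-2 B chains; doublets
    get >2 distinct recombinants on at least one locus; gamma-delta cells
    get >=1 G and >=1 D chain and no alpha-beta pair; no-TCR cells get zero
    chains.  Returns ``(table, labels)`` where ``labels`` maps each cell to
    its planted category in {"ab", "doublet", "gd", "no_tcr"}.
    """
    if isinstance(cell_ids, pd.DataFrame):
        cell_ids = cell_ids.index
    cell_ids = list(cell_ids)
    rates = (doublet_rate, gd_rate, no_tcr_rate)
    if any(r < 0 for r in rates) or sum(rates) > 1.0:
        raise ValueError("rates must be non-negative and sum to at most 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(
        ["doublet", "gd", "no_tcr", "ab"],
        size=len(cell_ids),
        p=[doublet_rate, gd_rate, no_tcr_rate, 1.0 - sum(rates)],
    )
    rows = []

    def add(cell, locus, n, productive=1):
        for _ in range(n):
            rows.append((cell, locus, productive, _random_cdr3(rng)))

    for cell, lab in zip(cell_ids, labels):
        if lab == "no_tcr":
            continue
        if lab == "ab":
            add(cell, "A", int(rng.integers(1, 3)))
            add(cell, "B", int(rng.integers(1, 3)))
        elif lab == "gd":
            add(cell, "G", int(rng.integers(1, 3)))
            add(cell, "D", int(rng.integers(1, 3)))
        else:  # doublet: >2 recombinants on at least one locus
            locus = str(rng.choice(["A", "B"]))
            other = "B" if locus == "A" else "A"
            add(cell, locus, int(rng.integers(3, 5)))
            add(cell, other, int(rng.integers(1, 3)))
    table = pd.DataFrame(rows, columns=["cell_id", "locus", "productive", "cdr3"])
    return table, pd.Series(labels, index=pd.Index(cell_ids, name="cell_id"), name="tcr_truth")


# ---------------------------------------------------------------------------
# cross-species marker tables
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPair:
    """Paired-species marker/expression tables with planted truth."""

    markers_a: pd.DataFrame
    markers_b: pd.DataFrame
    stats_a: pd.DataFrame
    stats_b: pd.DataFrame
    ortholog_map: pd.DataFrame
    families: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_species_pair(n_orthologs: int, n_paralog_swaps: int, seed: int,
                          n_shared_markers: int = 20, n_a_only: int = 10,
                          n_b_only: int = 10, n_decoy_families: int = 20) -> SpeciesPair:
    """NLT marker tables for two species linked by one-to-one orthologs.

    Plants ``n_shared_markers`` markers conserved through orthology,
    species-private markers, ``n_paralog_swaps`` paralog-substitution events
    (gene g is an NLT marker in species A and silent in B while its family
    paralog g' shows the mirror pattern) and ``n_decoy_families`` paralog
    families without a substitution pattern.
    """
    for cnt in (n_orthologs, n_paralog_swaps, n_shared_markers, n_a_only, n_b_only,
                n_decoy_families):
        if cnt < 0:
            raise ValueError("counts must be >= 0")
    need = n_shared_markers + n_a_only + n_b_only + 2 * (n_paralog_swaps + n_decoy_families)
    if n_orthologs < need:
        raise ValueError(f"n_orthologs={n_orthologs} too small; need >= {need}")
    rng = np.random.default_rng(seed)

    genes_a = [f"GA{i:05d}" for i in range(n_orthologs)]
    genes_b = [f"GB{i:05d}" for i in range(n_orthologs)]
    omap = pd.DataFrame(
        {"gene_a": genes_a, "gene_b": genes_b, "homology_type": "one2one", "family_id": ""}
    )

    idx = iter(range(n_orthologs))
    shared = [next(idx) for _ in range(n_shared_markers)]
    a_only = [next(idx) for _ in range(n_a_only)]
    b_only = [next(idx) for _ in range(n_b_only)]
    swap_fams = [(next(idx), next(idx)) for _ in range(n_paralog_swaps)]
    decoy_fams = [(next(idx), next(idx)) for _ in range(n_decoy_families)]

    # expression fraction of each gene in NLT cells, per species
    pct_a = rng.uniform(0.0, 0.03, n_orthologs)
    pct_b = rng.uniform(0.0, 0.03, n_orthologs)
    marker_a = np.zeros(n_orthologs, bool)
    marker_b = np.zeros(n_orthologs, bool)

    def plant(i, in_a, in_b):
        if in_a:
            marker_a[i] = True
            pct_a[i] = rng.uniform(0.4, 0.9)
        if in_b:
            marker_b[i] = True
            pct_b[i] = rng.uniform(0.4, 0.9)

    for i in shared:
        plant(i, True, True)
    for i in a_only:
        plant(i, True, False)
    for i in b_only:
        plant(i, False, True)

    fam_rows = []
    for fi, (i, j) in enumerate(swap_fams):
        # gene i: marker in A, silent in B; paralog j: marker in B, silent in A
        plant(i, True, False)
        plant(j, False, True)
        fam_rows += [(genes_a[i], genes_b[i], f"swap{fi}"), (genes_a[j], genes_b[j], f"swap{fi}")]
    for fi, (i, j) in enumerate(decoy_fams):
        kind = fi % 3
        if kind == 0:  # half swap: one member marker+silent, partner silent everywhere
            plant(i, True, False)
        elif kind == 1:  # swap-like markers but neither gene silent in the other species
            plant(i, True, False)
            plant(j, False, True)
            pct_b[i] = rng.uniform(0.2, 0.4)
            pct_a[j] = rng.uniform(0.2, 0.4)
        # kind == 2: both members silent everywhere
        fam_rows += [(genes_a[i], genes_b[i], f"decoy{fi}"), (genes_a[j], genes_b[j], f"decoy{fi}")]
    families = pd.DataFrame(fam_rows, columns=["gene_a", "gene_b", "family_id"])

    def marker_table(genes, marker, pct):
        m = pd.DataFrame(
            {
                "gene": genes,
                "avg_logFC": np.where(marker, rng.uniform(0.5, 2.0, n_orthologs), 0.0),
                "pct_nlt": pct,
                "p_adj": np.where(marker, 1e-6, 1.0),
                "significant": marker,
            }
        ).set_index("gene", drop=False)
        return m[m["significant"]]

    stats_a = pd.DataFrame({"gene": genes_a, "pct_nlt": pct_a}).set_index("gene", drop=False)
    stats_b = pd.DataFrame({"gene": genes_b, "pct_nlt": pct_b}).set_index("gene", drop=False)
    truth = {
        "shared_markers": [(genes_a[i], genes_b[i]) for i in shared],
        "swap_pairs": [(genes_a[i], genes_b[j]) for i, j in swap_fams],
    }
    return SpeciesPair(
        markers_a=marker_table(genes_a, marker_a, pct_a),
        markers_b=marker_table(genes_b, marker_b, pct_b),
        stats_a=stats_a,
        stats_b=stats_b,
        ortholog_map=omap,
        families=families,
        truth=truth,
    )
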