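"""GPLVM pseudospace: ordering recovery is the contract (scale and sign of
the latent coordinates are unidentifiable)."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.stats import spearmanr

from tregtraj.synthetic import SimConfig, generate_trajectory_dataset
from tregtraj.trajectory import (
    _neg_objective,
    _pack,
    fit_gplvm,
    fit_partitioned_gplvm,
    lv_gene_correlation,
    project_cells,
    shared_proportion,
)


@pytest.fixture(scope="module")
def single_axis():
    """200 cells x 100 genes driven by one planted coordinate."""
    cfg = SimConfig(n_cells_per_group=100, n_switch_genes=100, n_flat_genes=0,
                    n_marker_genes_per_group=0, n_cellcycle_genes=0,
                    n_background_genes=0, noise="gaussian", gaussian_sd=0.3, seed=3)
    adata, truth = generate_trajectory_dataset(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="module")
def single_axis_fit(single_axis):
    _, adata, _ = single_axis
    nlt = (adata.obs["group"] == "NLT-like").to_numpy()
    emb = fit_gplvm(adata.X, q_latent=6, seed=0, tissue_nlt=nlt, max_iter=400)
    return adata, emb


class TestObjective:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        N, Q, D = 10, 3, 6
        X = rng.standard_normal((N, Q))
        Y = rng.standard_normal((N, D))
        Y2 = rng.standard_normal((N, 4))
        hyp = [(0.1, np.array([0.2, -0.3, 0.1]), -0.5),
               (0.0, np.array([-0.1, 0.4, 0.0]), -1.0)]
        theta = _pack(X, hyp)
        Ss, Ds = [Y @ Y.T, Y2 @ Y2.T], [D, 4]
        _, g = _neg_objective(theta, Ss, Ds, N, Q)
        gn = approx_fprime(theta, lambda th: _neg_objective(th, Ss, Ds, N, Q)[0], 1e-6)
        assert np.max(np.abs(g - gn)) / np.max(np.abs(gn)) < 1e-4


class TestFit:
    def test_single_axis_recovery(self, single_axis, single_axis_fit):
        _, _, _ = single_axis
        adata, emb = single_axis_fit
        t = adata.obs["true_t"].to_numpy()
        rel = emb.relevance[0]
        # one dominant relevance weight; remaining dims jointly < 20%
        assert rel.argmax() == emb.lv_index
        assert rel.sum() - rel.max() < 0.2 * rel.sum()
        assert abs(spearmanr(emb.lv0, t).statistic) >= 0.9
        # orientation: NLT pole high
        nlt = (adata.obs["group"] == "NLT-like").to_numpy()
        assert emb.lv0[nlt].mean() > emb.lv0[~nlt].mean()

    def test_gene_duplication_preserves_ordering(self, single_axis):
        _, adata, _ = single_axis
        Y = np.asarray(adata.X)[:, :40]
        e1 = fit_gplvm(Y, q_latent=3, seed=0, max_iter=250)
        e2 = fit_gplvm(np.hstack([Y, Y]), q_latent=3, seed=0, max_iter=250)
        rho = spearmanr(e1.X[:, e1.lv_index], e2.X[:, e2.lv_index]).statistic
        assert abs(rho) >= 0.95

    def test_pure_noise_has_no_dominant_dimension(self, rng):
        Y = rng.standard_normal((60, 40))
        emb = fit_gplvm(Y, q_latent=6, seed=0, max_iter=250)
        rel = emb.relevance[0]
        assert rel.max() <= 3.0 * np.median(rel)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_gplvm(np.ones((30, 10)), q_latent=2)

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gplvm(rng.standard_normal((10, 5)), q_latent=2)


class TestProjection:
    def test_training_cells_project_onto_themselves(self, single_axis_fit):
        adata, emb = single_axis_fit
        sub = np.asarray(adata.X)[:50]
        X_proj = project_cells(emb, sub)
        rho = spearmanr(X_proj[:, emb.lv_index], emb.X[:50, emb.lv_index]).statistic
        assert rho >= 0.99

    def test_heldout_tissue_joins_the_same_ordering(self, single_axis, single_axis_fit):
        from dataclasses import replace
        from tregtraj.synthetic import generate_from_truth
        cfg, _, truth = single_axis
        adata, emb = single_axis_fit
        cfg2 = replace(cfg, n_cells_per_group=50,
                       groups=(("LT-like", "bLN", (0.0, 0.6)),
                               ("NLT-like", "skin", (0.4, 1.0))))
        held = generate_from_truth(cfg2, truth, seed=17, cell_prefix="held")
        Xq = project_cells(emb, held.X)
        lv = np.concatenate([emb.lv0, emb.sign * Xq[:, emb.lv_index]])
        t = np.concatenate([adata.obs["true_t"], held.obs["true_t"]])
        assert abs(spearmanr(lv, t).statistic) >= 0.85

    def test_noise_cells_stay_on_the_prior_scale(self, single_axis_fit, rng):
        # cells carrying no trajectory signal cannot be placed by the
        # likelihood; the unit latent prior keeps their coordinates bounded
        # on its own scale (they sit off the data manifold but do not
        # diverge, and they do not reach the trajectory's poles)
        adata, emb = single_axis_fit
        Y = np.asarray(adata.X)
        noise = Y.mean(0) + rng.standard_normal((20, adata.n_vars)) * Y.std(0) * 3
        Xq = project_cells(emb, noise)
        per_dim = np.abs(Xq).mean()
        assert per_dim < 1.0  # well within the N(0, 1) latent prior


class TestPartitioned:
    @pytest.fixture(scope="class")
    def mrd_fit(self):
        cfg = SimConfig(n_cells_per_group=100, n_switch_genes=40, n_flat_genes=30,
                        n_marker_genes_per_group=15, n_cellcycle_genes=20,
                        n_background_genes=0, noise="gaussian", gaussian_sd=0.3,
                        cycling_fraction=0.3, seed=5)
        adata, truth = generate_trajectory_dataset(cfg)
        parts = {
            "cellcycle": adata[:, truth.index[truth["klass"] == "cellcycle"]].X,
            "tissue_markers": adata[:, truth.index[truth["klass"] == "marker"]].X,
            "rest": adata[:, truth.index[truth["klass"].isin(["switch", "flat"])]].X,
        }
        nlt = (adata.obs["group"] == "NLT-like").to_numpy()
        emb, rel = fit_partitioned_gplvm(parts, q_latent=12, seed=0,
                                         tissue_nlt=nlt, max_iter=500)
        return adata, emb, rel

    def test_adaptation_and_cycle_factors_separate(self, mrd_fit):
        from sklearn.metrics import roc_auc_score
        adata, emb, rel = mrd_fit
        t = adata.obs["true_t"].to_numpy()
        assert abs(spearmanr(emb.lv0, t).statistic) >= 0.85
        cyc_lv = emb.trace["cellcycle_lv"]
        assert cyc_lv != emb.lv_index
        auc = roc_auc_score(adata.obs["cycling"], emb.X[:, cyc_lv])
        assert max(auc, 1 - auc) >= 0.9

    def test_flat_cellcycle_partition_degrades_to_plain_relevance(self, rng):
        n = 60
        t = rng.uniform(0, 1, n)
        signal = np.outer(t, rng.uniform(0.5, 2.0, 20)) + rng.normal(0, 0.2, (n, 20))
        flat = rng.normal(1.0, 0.2, (n, 10))
        rest = np.outer(t, rng.uniform(0.5, 2.0, 10)) + rng.normal(0, 0.2, (n, 10))
        emb, rel = fit_partitioned_gplvm(
            {"cellcycle": flat, "tissue_markers": signal, "rest": rest},
            q_latent=4, seed=0, max_iter=300)
        share = emb.relevance[1] / emb.relevance[1].sum()
        assert emb.lv_index == int(np.argmax(share))
        assert abs(spearmanr(emb.X[:, emb.lv_index], t).statistic) >= 0.8

    def test_empty_partition_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_partitioned_gplvm({"cellcycle": rng.normal(size=(30, 0)),
                                   "tissue_markers": rng.normal(size=(30, 5)),
                                   "rest": rng.normal(size=(30, 5))}, q_latent=2)


class TestLVCorrelation:
    def test_gene_equal_to_lv_has_r_one(self, rng):
        lv = rng.uniform(0, 1, 100)
        X = np.column_stack([lv, rng.normal(size=100)])
        out = lv_gene_correlation(X, lv, gene_ids=["self", "noise"])
        assert out.loc["self", "r"] == pytest.approx(1.0)
        assert out.loc["self", "flagged"]

    def test_planted_monotone_gene_flagged(self, rng):
        from tregtraj.synthetic import sigmoid_mean
        t = rng.uniform(0, 1, 500)
        g = sigmoid_mean(t, 1.0, 8.0, 0.5) + rng.normal(0, 0.5, 500)
        out = lv_gene_correlation(g[:, None], t, gene_ids=["sw"])
        assert out.loc["sw", "r"] > 0.25

    def test_zero_variance_lv_rejected(self, rng):
        with pytest.raises(ValueError):
            lv_gene_correlation(rng.normal(size=(10, 2)), np.ones(10))

    def test_shared_proportion_of_identical_sets_is_100(self):
        assert shared_proportion({"a", "b"}, {"b", "a"}) == 100.0
        assert shared_proportion({"a", "b"}, {"b", "c"}) == 50.0
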