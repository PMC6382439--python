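"""Sigmoid switch-gene fitting: closed forms, symmetry, filters,
subsample-median scheme."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tregtraj.kinetics import (
    _balanced_subsample,
    fit_all_switch_genes,
    fit_switch_gene,
    shared_switch_genes,
    sigmoid,
    subsample_median_fit,
)


class TestSigmoid:
    def test_closed_forms(self):
        assert sigmoid(0.5, 1.7, 3.0, 0.5) == pytest.approx(1.7)  # S(t0) = mu0
        assert sigmoid(0.5 + np.log(3), 1.0, 1.0, 0.5) == pytest.approx(1.5)
        assert sigmoid(0.5, 1.0, 1.0, 0.5 - np.log(3)) == pytest.approx(1.5)

    def test_step_limits_are_numerically_safe(self):
        assert sigmoid(0.6, 2.0, 1e9, 0.5) == pytest.approx(4.0)
        assert sigmoid(0.4, 2.0, 1e9, 0.5) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-5, 5), st.floats(0.01, 10), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_twice_mu0(self, t, mu0, k):
        s = sigmoid(t, mu0, k, 0.0)
        assert 0.0 <= s <= 2 * mu0 + 1e-12


class TestFitSwitchGene:
    def test_planted_parameters_recovered(self, rng):
        t = rng.uniform(0, 1, 500)
        y = sigmoid(t, 2.0, 10.0, 0.5) + rng.normal(0, 0.1, 500)
        fit = fit_switch_gene(y, t)
        assert abs(fit.t0 - 0.5) <= 0.05
        assert fit.k > 0 and fit.direction == "activation"
        assert fit.mu0 == pytest.approx(2.0, abs=0.2)
        assert fit.p_raw < 1e-10

    def test_flat_gene_is_null(self, rng):
        t = rng.uniform(0, 1, 200)
        y = 1.3 + rng.normal(0, 0.1, 200)
        fit = fit_switch_gene(y, t)
        stat = 2 * (fit.loglik_sigmoid - fit.loglik_constant)
        assert stat < 8.0 and fit.p_raw > 0.1

    def test_time_reversal_symmetry(self, rng):
        t = rng.uniform(0, 1, 300)
        y = sigmoid(t, 1.5, 8.0, 0.4) + rng.normal(0, 0.1, 300)
        fwd = fit_switch_gene(y, t)
        rev = fit_switch_gene(y, -t)
        assert rev.k == pytest.approx(-fwd.k, rel=1e-2)
        assert rev.t0 == pytest.approx(-fwd.t0, abs=1e-2)
        assert rev.loglik_sigmoid == pytest.approx(fwd.loglik_sigmoid, abs=0.1)

    def test_sigmoid_loglik_never_below_constant(self, rng):
        t = rng.uniform(0, 1, 100)
        for _ in range(20):
            y = rng.normal(1.0, 0.5, 100)
            fit = fit_switch_gene(y, t)
            assert fit.loglik_sigmoid >= fit.loglik_constant - 1e-9

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_switch_gene(rng.normal(size=5), rng.uniform(size=5))


class TestFitAllSwitchGenes:
    def test_gene_below_prevalence_never_fitted(self, rng):
        t = rng.uniform(0, 1, 200)
        X = np.zeros((200, 2))
        X[:29, 0] = 3.0 * t[:29]            # expressed in 29 cells only
        X[:, 1] = sigmoid(t, 1.0, 10.0, 0.5) + np.abs(rng.normal(0, 0.1, 200))
        out = fit_all_switch_genes(X, t, gene_ids=["rare", "sw"], min_cells=30,
                                   min_abs_corr=0.0)
        assert "rare" not in out.index and "sw" in out.index

    def test_t0_outside_lv_range_not_reported(self, rng):
        t = rng.uniform(0, 1, 300)
        # half-sigmoid: switch point far beyond the observed range
        X = (sigmoid(t, 1.0, 3.0, 1.8) + rng.normal(0, 0.02, 300))[:, None] + 1.0
        out = fit_all_switch_genes(X, t, gene_ids=["g"], min_abs_corr=0.0)
        if len(out) and not (out["t0"].between(t.min(), t.max())).iloc[0]:
            assert not out["reported"].iloc[0]

    def test_exclusion_list_respected(self, rng):
        t = rng.uniform(0, 1, 100)
        X = np.column_stack([sigmoid(t, 1.0, 10.0, 0.5)] * 2) + rng.normal(0, 0.1, (100, 2))
        out = fit_all_switch_genes(X, t, gene_ids=["keep", "drop"],
                                   exclude_genes=["drop"])
        assert list(out["gene"]) == ["keep"]

    def test_bh_over_fitted_genes(self, rng):
        t = rng.uniform(0, 1, 200)
        X = np.column_stack([
            sigmoid(t, 1.0, 10.0, 0.5) + rng.normal(0, 0.1, 200),
            rng.normal(1.0, 0.3, (200,)),
            rng.normal(1.0, 0.3, (200,)),
        ])
        out = fit_all_switch_genes(X, t, gene_ids=["sw", "f1", "f2"], min_abs_corr=0.0)
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(out["p_raw"], method="fdr_bh")[1]
        np.testing.assert_allclose(out["q"], expected)


class TestSubsampleMedian:
    def test_single_full_round_equals_plain_fit(self, rng):
        t = rng.uniform(0, 1, 120)
        X = np.column_stack([sigmoid(t, 1.2, 9.0, 0.5) + rng.normal(0, 0.1, 120),
                             rng.normal(1.0, 0.2, 120)])
        groups = np.repeat(["a", "b"], 60)
        sub = subsample_median_fit(X, t, groups, gene_ids=["sw", "fl"], n_rounds=1,
                                   seed=0, min_abs_corr=0.0)
        plain = fit_all_switch_genes(X, t, gene_ids=["sw", "fl"], min_abs_corr=0.0)
        # balanced groups: the single round uses every cell, so parameters agree
        for g in sub.index:
            assert sub.loc[g, "t0"] == pytest.approx(plain.loc[g, "t0"], abs=1e-9)
            assert sub.loc[g, "k"] == pytest.approx(plain.loc[g, "k"], rel=1e-6)

    def test_each_round_matches_smallest_group_size(self, rng):
        groups = pd.Series(["big"] * 80 + ["small"] * 12)
        idx = _balanced_subsample(groups, 12, rng)
        picked = groups.iloc[idx]
        assert (picked.value_counts() == 12).all()
        assert len(idx) == 24 and len(set(idx)) == 24  # without replacement

    def test_median_fit_more_robust_than_single_fit_under_imbalance(self, rng):
        # 10:1 imbalanced groups; the balanced-subsample median of t0 over
        # rounds should not be worse than the single imbalanced fit
        errs_single, errs_median = [], []
        for rep in range(8):
            r = np.random.default_rng(rep)
            t = np.concatenate([r.uniform(0, 0.55, 200), r.uniform(0.45, 1, 20)])
            groups = np.array(["lt"] * 200 + ["nlt"] * 20)
            y = sigmoid(t, 1.0, 8.0, 0.55) + r.normal(0, 0.3, 220)
            single = fit_all_switch_genes(y[:, None], t, gene_ids=["g"],
                                          min_abs_corr=0.0)
            med = subsample_median_fit(y[:, None], t, groups, gene_ids=["g"],
                                       n_rounds=15, seed=rep, min_cells=10,
                                       min_abs_corr=0.0)
            if "g" in single.index and "g" in med.index:
                errs_single.append(abs(single.loc["g", "t0"] - 0.55))
                errs_median.append(abs(med.loc["g", "t0"] - 0.55))
        assert np.median(errs_median) <= np.median(errs_single) + 0.02

    def test_group_validation(self, rng):
        X = rng.normal(size=(30, 2))
        t = rng.uniform(size=30)
        with pytest.raises(ValueError):
            subsample_median_fit(X, t, np.repeat("only", 30))
        with pytest.raises(ValueError):
            subsample_median_fit(X, t, np.array(["a"] * 25 + ["b"] * 5))


class TestSharedSwitchGenes:
    def _table(self, genes, t0=0.5):
        return pd.DataFrame({"gene": genes, "t0": t0,
                             "reported": True}).set_index("gene", drop=False)

    def test_disjoint_tables_share_nothing(self):
        out = shared_switch_genes(self._table(["a", "b"]), self._table(["c"]))
        assert out["n_shared"] == 0 and out["shared"] == []

    def test_identical_tables_share_everything(self):
        out = shared_switch_genes(self._table(["a", "b"]), self._table(["b", "a"]))
        assert out["n_shared"] == 2 and out["n_a"] == out["n_b"] == 2

    def test_t0_pairs_joined_per_gene(self):
        a = self._table(["x", "y"], t0=0.3)
        b = self._table(["y", "z"], t0=0.7)
        out = shared_switch_genes(a, b)
        assert out["shared"] == ["y"]
        assert out["t0_pairs"].loc["y", "t0_a"] == 0.3
        assert out["t0_pairs"].loc["y", "t0_b"] == 0.7
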