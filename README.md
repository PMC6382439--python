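# tregtraj

Regulatory T cells (Tregs) that keep non-lymphoid tissues (NLT — skin,
colon lamina propria) in check are recruited from lymphoid tissues (LT —
spleen, lymph nodes) and adapt their transcriptional program on the way.
`tregtraj` implements the computational pipeline for studying that
adaptation from single-cell RNA-seq: it orders cells along a
one-dimensional LT→NLT *pseudospace* coordinate and describes the gene
cascade along it as a sequence of switch-like events.

The stages, each usable on its own:

* **QC** — UMI/gene count filters plus TCR-based rules (remove cells
  without a reconstructed TCR, doublets with >2 recombinants per locus,
  and γδ T cells), log-normalization, and binned-dispersion variable-gene
  selection.
* **Markers & signatures** — Wilcoxon differential expression with
  Bonferroni correction and Seurat-style fold-changes, a two-pass union
  scheme for comparable contrasts, and the NLT/LT signature ratio score.
* **Label transfer** — L1-penalised one-vs-rest logistic regression mapping
  query cells to reference subpopulations.
* **Trajectory** — a Gaussian process latent variable model (GPLVM) with
  automatic relevance determination (ARD) infers the pseudospace; held-out
  cells are projected into it; a partitioned (MRD) variant separates
  cell-cycle from tissue-adaptation variation.
* **Switch kinetics** — each gene's expression along the coordinate t is
  fitted by maximum likelihood to the sigmoid

      S(t) = 2·μ0 / (1 + e^(−k(t − t0)))

  where μ0 is the mean expression between the on and off states, t0 the
  switch point and the sign of k the direction (activation/inhibition),
  with a likelihood-ratio test against a flat profile, BH correction, the
  prevalence and correlation pre-filters and a subsample-median scheme
  for unbalanced subpopulations.
* **Program ordering** — hypergeometric gene-set enrichment of the switch
  genes, mean-t0 timing per program, and Spearman comparisons of program
  order across trajectories and of per-gene t0 across conditions.
* **Cross-species** — marker overlap through one-to-one orthologs,
  fold-change concordance, and detection of paralog substitutions (the
  NLT-marker role swapping between family members across species).

Everything is exercisable without external data through a bundled
synthetic-data generator that plants ground truth (true coordinates,
switch parameters, marker blocks, TCR categories, paralog swaps) under
negative-binomial count noise. See `docs/methods.md` for the models and
their assumptions.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import tregtraj as tt

# a planted LT->NLT trajectory: 200 cells, 100 switch genes, one axis
cfg = tt.SimConfig(n_cells_per_group=100, n_switch_genes=100, n_flat_genes=0,
                   n_marker_genes_per_group=0, n_cellcycle_genes=0,
                   n_background_genes=0, noise="gaussian", gaussian_sd=0.3,
                   seed=3)
adata, truth = tt.generate_trajectory_dataset(cfg)

nlt = (adata.obs["group"] == "NLT-like").to_numpy()
emb = tt.fit_gplvm(adata.X, q_latent=6, seed=0, tissue_nlt=nlt)
rho = spearmanr(emb.lv0, adata.obs["true_t"]).statistic
print(f"LV{emb.lv_index} vs planted coordinate: rho = {rho:.3f}")

fits = tt.fit_all_switch_genes(adata.X, emb.lv0,
                               gene_ids=list(adata.var_names))
reported = fits[fits["reported"]]
print(f"{len(reported)} switch genes reported of {len(fits)} fitted")
```

prints

```
LV0 vs planted coordinate: rho = 0.998
99 switch genes reported of 100 fitted
```

meaning the most relevant ARD dimension reproduces the planted cell
ordering almost exactly, and the sigmoid stage recovers nearly all planted
switch genes at q ≤ 0.05 along the *inferred* (not true) coordinate.

## Command line

The same stages run as a pipeline with config, manifests and fixed seeds:

```sh
tregtraj all --outdir out --seed 1          # synthetic end-to-end
tregtraj simulate --outdir out --seed 1     # or stage by stage
tregtraj qc --outdir out
tregtraj trajectory --outdir out
tregtraj kinetics --outdir out
```

All thresholds can be set in a YAML config (`--config cfg.yaml`); each
stage writes TSV/JSON artifacts and a `manifest_<stage>.json` recording
the seed, versions and input hashes.

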