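# Methods

`tregtraj` reconstructs the computational arc of a cross-tissue regulatory
T cell (Treg) adaptation analysis: order cells along a one-dimensional
lymphoid-to-non-lymphoid (LT→NLT) pseudospace coordinate inferred from
single-cell expression, and describe the transcriptional cascade along it
as a sequence of switch-like gene events. This note documents the models,
the defaults and why they were chosen, the synthetic data the package is
validated on, and the limits of what those validations show.

## Quality control

Droplet-style QC keeps cells with 1000–15000 total UMIs and 700–3500
detected genes (≥1 UMI), both bounds inclusive. The phrase "between a and
b" is read as inclusive; the bounds are configurable, so an exclusive
reading costs one unit at each edge. Mitochondrial content is deliberately
not filtered.

TCR-based rules consume a reconstructed-chain table. A *recombinant* is a
distinct (locus, CDR3) pair; unproductive chains count toward the tally,
since a doublet's excess recombination events are informative regardless of
productivity. A cell is a `doublet` if any locus carries more than two
distinct recombinants (one cell has at most two recombined alleles per
locus); `gd` if it has at least one γ and one δ chain and no αβ pair;
`no_tcr` if it has no chain at all. Precedence for reporting a single
reason per cell: low_umi → high_umi → low_genes → high_genes → no_tcr →
tcr_doublet → gd_tcell. iNKT-like cells have no chain-level rule; they are
removed via a caller-supplied cluster exclusion list, not a classifier.

Normalization is `x = ln(1 + 10^4 · c / total)` (natural log, scale factor
10⁴), so zero counts map exactly to zero.

### Variable genes

Genes are ranked by a binned dispersion z-score with `num_bins = 100`
equal-frequency bins. Mean and dispersion follow the droplet-toolkit
convention and are computed on the *de-logged* scale —
`mean = ln(mean(eˣ−1)+1)`, `dispersion = ln(var(eˣ−1)/mean(eˣ−1))` —
because the log-normalized scale compresses precisely the biological
variance being sought. Two numerical choices matter:

* The within-bin z-score is **robust** (median/MAD, default) rather than
  mean/sd. When a dataset has few truly variable genes, several of them
  land in one mean bin and inflate that bin's own mean and standard
  deviation, suppressing exactly the genes being sought; the robust
  location/scale is insensitive to them. `robust=False` restores the
  plain z-score.
* Ties are broken deterministically by gene identifier.

## Differential expression and signatures

Two-sided Wilcoxon rank-sum tests (tie-corrected normal approximation) on
log-normalized values; Bonferroni correction over the genes tested in each
contrast; fold-change as `ln(mean(eˣ−1)+1)_A − ln(mean(eˣ−1)+1)_B`. A gene
is tested when expressed (value > 0) in ≥5% of either group (a configurable
1% fallback serves whole-dataset cross-tissue contrasts; the caller
decides when it applies).
Significance: |logFC| ≥ 0.25 and adjusted p ≤ 0.05. The two-pass union
scheme records each contrast's tested set in pass one and re-tests every
contrast on the union in pass two, making p-values comparable across
contrasts of one family.

The NLT/LT signature score of a cluster counts the NLT- and LT-signature
genes among its significant upregulated markers and reports
`n_NLT / max(n_LT, 1)`. The denominator floor handles the zero-denominator
case; both raw counts are always
reported so any alternative can be recomputed. Signature gene sets are
inputs, never hard-coded.

## Label transfer

A logistic regression with L1 penalty, one-vs-rest, on raw counts
(`C = 1.0`, liblinear, seeded). Raw counts are the default input scale;
a normalized-input option exists because the input scale changes the
coefficients. Query cells receive the argmax-probability label; cells with
maximum probability < 0.5 carry an additive low-confidence flag that never
changes the label. Composition matrices are row-normalized percentage
cross-tabulations of predicted label by query subpopulation.

## Pseudospace: GPLVM with ARD

Cells receive latent coordinates `X ∈ R^{N×Q}` (Q = 6 by default); each
standardized gene is a GP over the latent space with an ARD
exponentiated-quadratic kernel

    k(x, x') = σ_f² exp(−½ Σ_q α_q (x_q − x'_q)²) + σ_n² δ.

Inference is MAP: latent points and kernel hyperparameters jointly maximise
the GP marginal likelihood plus a unit Gaussian prior on X, initialised
from PCA, optimised with L-BFGS (jitter 10⁻⁶, default 1500 iterations,
seed-controlled initialisation noise). The contract of this module is
*ordering*, not coordinates: latent scale and sign are unidentifiable, so
every validation uses rank correlation against planted truth. A
variational backend could be slotted in behind the same interface.

Genes are centred and unit-scaled before fitting: standardization makes
the shared kernel variance meaningful across genes of very different
magnitudes.

**Relevance.** ARD relevance is reported as `α_q · Var(X_q)` rather than
raw `α_q`. Under MAP with a latent prior, a dimension the model abandons
collapses to `Var(X_q) → 0` while its raw `α_q` remains arbitrary; the
variance-scaled weight is the scale-invariant quantity that actually ranks
dimensions by use.

**Selection and orientation.** The adaptation dimension ("LV0") is the
most relevant dimension whose ordering correlates with tissue identity
(point-biserial |r| ≥ 0.3 against the LT/NLT label, configurable), and its
sign is set so the NLT pole is high. Without labels, the most relevant
dimension is taken with positive orientation. Spleen-style tissue
exclusions are the caller's responsibility via metadata filtering.

**Projection.** Held-out cells are placed by optimising, per cell, the
trained model's GP predictive likelihood over the new latent position with
hyperparameters frozen (warm-started from the most similar training cell
and from the origin). Cells carrying no trajectory signal cannot be placed
by the likelihood and end up bounded by the unit prior, off the data
manifold — they do not reach the trajectory's poles.

**Partitioned variant (MRD).** Three gene sections — cell-cycle genes,
tissue marker genes, the rest — share latent coordinates but carry their
own kernel hyperparameters, hence their own relevance profiles
(Q = 12 by default). The adaptation dimension maximises the tissue-marker
relevance share among dimensions whose cell-cycle share is below twice the
uniform share (2/Q, configurable); if nothing qualifies the constraint is
dropped, which is also what happens naturally when the cell-cycle section
contains no cycle signal. The cell-cycle gene list is an input; the
package does not assign cycle phases.

## Switch-like genes

Expression along the coordinate t is modelled as

    S(t) = 2·μ0 / (1 + e^(−k(t − t0)))

with μ0 the mean expression between the on and off states, t0 the switch
point and k the signed activation strength (activation if k > 0,
inhibition if k < 0). Parameters maximise a Gaussian likelihood with
constant, profiled variance. The likelihood-ratio test against the
constant-mean model uses χ² with 2 degrees of freedom (three mean
parameters versus one; the variance is profiled in both). At the k = 0
boundary t0 is unidentified, so this reference distribution is
conservative — under a global null far fewer than 5% of genes reach
p ≤ 0.05, and Benjamini–Hochberg keeps the discovery fraction near zero.

Optimisation is deterministic multi-start least squares (trust-region
reflective with analytic Jacobian): t0 starts at the 20/50/80% quantiles
of t, k at {±1, ±10, ±100}/range(t) — the steep starts cover near-step
switches — and μ0 at the mean expression; |k| is bounded by 10⁴/range(t).
If the best sigmoid falls below the constant model the boundary fit (k=0)
is reported, so `loglik_sigmoid ≥ loglik_constant` always.

Pre-filters keep the fits to informative genes: genes expressed in ≥30 cells *and*
with |Pearson r| > 0.25 against the coordinate are fitted; BH q-values are
computed over the fitted set; fits are reported when q ≤ 0.05 and t0 lies
within the coordinate's range. An optional exclusion gene list mirrors the
"non-memory-cell-specific genes" pre-filter. For unbalanced
subpopulations, the subsample-median scheme refits `n_rounds = 100` times
on balanced subsamples matching the smallest subpopulation, reports
element-wise parameter medians over the rounds in which a gene was fitted,
and keeps genes passing the filters in more than half the rounds. The
q-value is aggregated across rounds by the same rule as the parameters:
the median.

## Program ordering

Gene-set enrichment among the reported switch genes is a plain one-sided
hypergeometric test with BH correction over the tested sets — a deliberate
divergence from the cited tool's hierarchical GO filtering, which is out
of scope; sets are taken verbatim from the GMT. Program timing is the
mean t0 over a term's switch-reported members regardless of direction
(per-direction means are also emitted); terms with fewer than two members
are dropped. Orderings from two trajectories are compared by Spearman's ρ
over shared terms' mean t0, with an exact permutation p-value when ≤10
terms are shared (full enumeration) and the asymptotic p otherwise.
Condition comparisons report per-gene Δt0, a Welch two-sample t test (the
paired variant is reported alongside, flagged separately, since gene
pairing exists), Spearman's ρ over the (t0_A, t0_B) pairs, and
per-category mean ± SE of Δt0. Identical inputs yield p = 1 by
convention (the t statistic is 0/0).

## Cross-species comparison

Marker overlap is computed through one-to-one orthologs only, after
case-normalising identifiers; fold-change concordance joins per-gene
NLT-vs-LT log fold-changes and reports the sign-concordance fraction. A
paralog substitution is reported for an ordered pair (g, g′) within one
paralog family when g is a significant NLT marker in species A and
detected in fewer than 5% of species B's NLT cells (`silent_frac`,
configurable — "not expressed" needs an explicit cutoff), while g′ shows
the mirror pattern. Reference LT compartments (blood vs spleen) are the
caller's choice via metadata. Orthology itself is an input, never
computed.

## Synthetic data

The generator emulates the study design so every stage is testable without
downloads: cells from ordered groups (default two, LT-like and NLT-like)
with true coordinates drawn uniformly from overlapping windows
([0, 0.6] and [0.4, 1]) to reproduce the continuous transition; switch
genes with planted (μ0, k, t0); flat genes; per-group marker genes; a
cell-cycle program carried by a random cell subset (25% by default); and a
background compartment of housekeeping-level genes.

In the two-group design, tissue markers are *graded* — steep sigmoids of t
switching at the window-overlap midpoint, rising toward the NLT pole for
NLT markers and falling for LT markers — mirroring markers that change
continuously across the transition rather than stepping at a tissue
boundary. With three or more groups markers are flat blocks over their
owner group.

Two noise models:

* **Negative-binomial counts** (default): rate
  `λ_cg = lib_c · μ_g(t_c)`, dispersion φ = 0.5 (var = μ + φμ²), library
  sizes log-normal (median 5000 UMIs, log-sd 0.25), optional extra
  Bernoulli dropout. Signal-gene rates are *calibrated* by numerical
  inversion so that the expected log-normalized expression equals the
  planted S(t) at the nominal depth — without calibration the
  discreteness/Jensen bias of `ln(1 + 10⁴c/total)` sits at −0.2 to −0.3
  for μ0 ≈ 1. Calibrating every gene is infeasible (per realized cell
  `Σ_g expm1(x) ≡ 10⁴` identically, while Jensen's inequality pushes the
  expectation of that sum above the planted one), so the background
  compartment absorbs the slack: its levels fill the remaining library
  budget and its own planted levels are not analysed. Background levels
  are log-normal, capped at 4 on the normalized scale so that no single
  gene dominates the library.
* **Gaussian**: the normalized-scale matrix directly,
  `x = S(t) + N(0, sd)` — the idealised setting in which the sigmoid
  likelihood is exactly specified; used for the fitting-stage validations
  (sd 0.1–0.3).

TCR tables plant clean αβ cells (1–2 productive α and β chains), doublets
(>2 distinct recombinants on a locus), γδ cells (γ+δ, no αβ pair) and
TCR-less cells at configurable rates; CDR3s are arbitrary strings. The
species-pair generator plants conserved markers, species-private markers,
paralog-substitution events and three kinds of near-miss decoy families
(half swaps, swap-like patterns without silence, fully silent families).

One seeded `numpy.random.Generator` drives all draws; identical
configuration and seed reproduce every output bit for bit.

**What the generator does not emulate** — batch effects, ambient RNA,
doublet expression profiles (TCR doublets are chain-level only), realistic
CDR3 sequences, cell-cycle phase structure (cycling is binary), spatial or
clonal structure, and gene–gene correlation beyond the shared latent
coordinate. Passing the bundled validations therefore shows that the
implementation recovers what was planted under over-dispersed count noise;
it does not show robustness to artefacts absent from the simulation.

## Validation scales

The bundled checks run at desk scale, chosen to finish in minutes on one
CPU while keeping each estimate well away from its decision boundary:
sigmoid recovery on 200 genes × 500 cells; FDR calibration on 1000 flat
genes × 400 cells; GPLVM recovery on 200 cells × 100 genes (Q = 6) with a
100-cell held-out projection; the partitioned model on 200 cells × 105
genes (Q = 12); condition-comparison calibration over 50–100 replicate
pairs; label transfer on 450 cells × 555 genes. The printed results of
the original study depend on its deposited datasets and are not
reproduced here.

## Known limitations

* MAP GPLVM can in principle hit local optima; PCA initialisation and the
  latent prior make the bundled recovery checks deterministic and stable,
  but pathological data may need restarts (`seed` varies the init).
* The sigmoid LRT's χ²(2) reference is conservative (boundary
  non-identifiability); power at small effect sizes is correspondingly
  reduced.
* The projection objective is a point estimate; it reports no per-cell
  uncertainty.
* `two_pass_union_de` waives the expression filter for union members in
  pass two, so very sparsely expressed genes can enter contrasts where
  their rank-sum test has little power.
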