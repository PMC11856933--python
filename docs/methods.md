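# Methods

This note documents the statistical procedures `trophicweb` implements,
the conventions chosen where several are defensible, what the synthetic
generator does and does not emulate, and known limitations.

## Network indices

All indices operate on a per-plot host×parasitoid matrix of parasitized
brood-cell counts (rows hosts, columns parasitoids — fixed orientation).

- **Generality / vulnerability** are weighted effective partner numbers,
  `Σ (A/m)·2^H` with `H` the Shannon entropy (bits) of a column/row.
  The effective-number base is 2 with bit entropies; for **interaction
  evenness** `E = −Σ p ln p / ln(I·J)` natural logs are used — the base
  cancels in the ratio. Zero cells are skipped everywhere (`0·log 0 ≡ 0`).
- **Linkage density** is exactly `(G + V)/2`, asserted to 1e-12 in tests.
- **Robustness (higher level)** is the trapezoidal area under the curve of
  the fraction of parasitoid species retaining ≥1 host as hosts are
  removed in uniformly random order, with endpoints (0,1) and (1,0). A
  parasitoid using `d` of `I` hosts is extinct after `k` removals with
  probability `C(I−d, k−d)/C(I, k)`, and because the trapezoidal area is
  linear in the expected curve, the average over all `I!` orders has this
  closed form. `all_indices` therefore reports the exact expectation for
  every matrix size, making the whole bundle deterministic. A Monte-Carlo
  estimator over sampled orders (default 500) and a full enumerator
  (feasible to I = 8, i.e. 40,320 orders) are retained and are verified to
  agree with the closed form.
- Degenerate 1×1 networks: evenness raises an error rather than returning
  NaN; the pipeline records NaN for that plot and excludes it from
  evenness models.

## Patefield null models

Null tables preserve both margins exactly and follow the multivariate
(Fisher–Yates) hypergeometric distribution — the classical null of
independent reassortment — sampled by sequential row-wise
multivariate-hypergeometric draws. This samples the target distribution
exactly, so no swap-chain burn-in or thinning decisions arise.
Significance per index is two-sided: double the smaller tail with the
add-one rule, capped at 1 (`p ≥ 1/(n_null+1)` always). When the null
distribution is degenerate (e.g. a forced table), the z-score is flagged
NaN and the tie rule yields p = 1. The per-plot tests default to 10,000
draws; the acceptance script scales this to 1,000 per plot, which leaves
the "plots departing from the null" counts essentially unchanged.

## Cophylogenetic congruence (ParaFit)

Principal coordinates of the host and parasitoid patristic matrices
(Gower centering; Lingoes correction if the smallest eigenvalue is below
−1e-8 relative) give coordinate matrices B and C; with the binary
parasitoid×host association A, the global statistic is `‖CᵀAB‖²_F`. The
null permutes each parasitoid's host assignments independently (random
host use); p is one-sided with the add-one rule. Count matrices are
accepted and binarized. Species without links must be pruned first —
silent inclusion would dilute the statistic. With a single host or
parasitoid the statistic is permutation-invariant and p = 1 is returned,
flagged. Per-link statistics (leave-one-link-out contributions) are
available but optional.

## Community phylogenetics

MPD excludes i=j pairs and normalizes by the summed pair weights; Rao's Q
is the plain quadratic entropy `Σ p_i p_j d_ij` without a denominator.
The two are stated separately because they are often conflated verbally;
the identity `RaoQ = MPD·(1 − Σp²)` is asserted in tests. MNTD weights
each species' nearest-neighbour distance by its relative abundance. Tree
metrics are weighted by wood volume. Functional distances are Euclidean
on per-trait z-scores divided by √(number of traits); the traits here are
all continuous, so Gower coefficients would add nothing. Zero-variance
traits are dropped with a warning; if none remain, distances are zero (so
Rao's Q collapses to 0 rather than erroring). No log-transformations are
applied before z-scoring.

Between-plot *phylogenetic composition* uses the inter-community MPD
`Σ_i Σ_k p_i q_k d_ik`, assembled for all plot pairs as `W d Wᵀ` with
row-normalized weights. Its diagonal (a plot's own MPD, not a
self-dissimilarity) is zeroed before rank-based ordination.

## Ordination and permutation tests

NMDS minimizes Kruskal stress-1 with monotone regression under the
primary tie treatment (ties in the dissimilarities are ordered by the
current configuration distances before isotonic fitting). Each start
iterates a Guttman transform followed by re-fitting of disparities and
accepts an update only if stress decreases, so the accepted stress
sequence is non-increasing by construction; convergence when the
improvement falls below 1e-6 or after 500 iterations. The metric PCoA
start plus 20 random restarts (default) are compared and the best kept.
Final scores are centered, rotated to principal axes (axis 1 carries
maximal variance) and sign-fixed for reproducibility. All-equal
dissimilarities are flagged degenerate with the PCoA configuration and
stress 0.

envfit z-scores each variable, regresses it on the two axis-score
columns, reports the normalized coefficient vector (arrow), the R², and a
permutation p over row permutations of the variable (999 by default).
Mantel correlates upper triangles (Pearson) with one-sided label
permutation. PERMANOVA partitions `trace(G)` of the Gower-centered
squared-dissimilarity matrix; each term is tested marginally (its SS is
the drop in explained trace when the term leaves the full model), with
pseudo-F against raw row permutations of G. Residual-permutation schemes
differ negligibly at these sample sizes; raw permutation keeps the
procedure exact under the intercept-only null, which is what the
calibration tests check (type-I error within [0.03, 0.07] at α = 0.05
over 500 simulations for all three tests).

## Regression stage

Continuous predictors are z-scored; tree species richness is
log2-transformed first (the design is a doubling series). Site stays
categorical. Full models offer site, diversity terms, canopy cover,
elevation, eastness/northness (sine/cosine of aspect), slope, and
site×diversity interactions. Tree species richness and tree MPD are never
offered to the same model (they are strongly collinear by design);
alternative models swap one for the other, enforced structurally.
AICc = AIC + 2k(k+1)/(n−k−1) with k counting all estimated parameters
including the residual variance.

Backward simplification drops, at each step, a term that is both
nonsignificant (no coefficient with p ≤ 0.05) and whose removal lowers
AICc, choosing the largest AICc improvement, never removing a main effect
while its interaction remains; it stops when no such drop exists. The
consequence — intentional — is that nonsignificant terms whose deviance
contribution exceeds the AICc penalty (roughly t² > 2.2, i.e. p below
~0.14) are retained in minimal models. A p-only elimination variant would
remove them; the dual rule was chosen because retaining such marginal
terms matches how minimal models in this literature typically look. The
returned model's AICc never exceeds the full model's.

## Synthetic data generator

The generator emulates the study design, not any particular dataset:

- 88 plots in two sites (site A: 8 plots each of richness 1, 2, 4, 8 plus
  6×16 and 2×24; site B the same plus 8 extra monocultures); 3
  monocultures are marked as lost to tree mortality, leaving 85 analysis
  plots. The 40-species tree pool splits 16/16 between sites with 8
  shared species completing the 24-mixtures.
- Plot compositions at low richness are phylogenetically clustered around
  a focal species (sampling weight `exp(−d/τ)`, `τ = 0.1·d̄·richness`).
  This is what produces the strong positive richness–MPD association that
  a nested diversity design exhibits; uniform subsets of a phylogeny
  would have size-independent expected MPD. Wood volumes are lognormal
  (σ = 0.6). Seven leaf traits are half Brownian on the tree phylogeny
  and half species-specific noise, reflecting partial phylogenetic
  conservatism.
- Hosts (56 species) and parasitoids (50) get pure-birth phylogenies and
  one latent Brownian trait each. A parasitoid's propensity for a host is
  logistic in the negative squared trait difference, thresholded per
  parasitoid so it accepts roughly its two best-matching hosts (falloff
  by the fifth), mixed with a flat background at weight
  `1 − phylo_signal_links` (default λ = 0.7). This strong specialization
  is what makes the per-plot webs depart from their Patefield nulls in
  most plots, as trap-nest networks do. `matched_trees=True` prunes the
  host tree for the parasitoids and copies the latent trait — a
  cospeciation scenario for power experiments.
- Per plot, host brood-cell totals are lognormal around 400 with a
  log-linear richness effect (β = 0.2); parasitized-cell totals are
  Poisson around 70 — the per-season catches of roughly 14 accumulate
  over the five pooled seasons — with a log-linear richness effect
  (β = 0.45) that also scales the active parasitoid pool (base 12
  species). Cells are multinomial over host-abundance × kernel weights.
  Canopy cover sharpens that cell distribution
  (`probs^exp(−β_canopy·z_canopy)`, β = −0.4), lowering measured
  interaction evenness under closed canopies. Canopy itself rises mildly
  with log richness (slope 0.025, noise 0.08); elevation differs by site;
  aspect is uniform, with eastness/northness its sine/cosine.
- All randomness derives from one seed through named CRC-hashed
  SeedSequence spawn keys, so any stage reproduces its draws in
  isolation; a fixed seed yields an identical dataset across runs.

What the generator does **not** emulate: multi-year structure (pooled
counts are drawn directly), observed species identities or abundance
ranks, spatial arrangement of plots, sampling incompleteness, and the
absolute scales of some indices (simulated generality runs higher than
typical field webs because the background link weight spreads a share of
cells across non-preferred hosts). Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of known
effects under a faithful *design*, not distributional realism of any
particular field dataset.

## Problem sizes and determinism

The test suite and the acceptance script use scaled stochastic sizes
chosen as the package's own defaults for routine validation: 199–999
permutations for calibration experiments, 1,000 Patefield draws per plot
in the acceptance run, 100 replicate datasets for sign-recovery. Exact
reproducibility holds bit-for-bit for a fixed seed on a given platform;
floating-point results are deterministic but, as usual, only stable to
numerical precision across BLAS builds.

## Known limitations

- PERMANOVA uses raw-row permutation, not residual permutation under the
  reduced model; with strong covariate imbalance and small n the two can
  differ.
- The NMDS engine is a standard alternating scheme; for pathological
  dissimilarity structures more restarts may be needed than the default.
- The AICc/significance dual drop rule retains marginally nonsignificant
  terms by design (see above); users wanting pure-AICc or pure-p
  elimination can call `fit_index_model` directly on their own term sets.
- Between-community MPD is not a metric; it is used only through its
  ranks (NMDS) and permutation tests, never as a Euclidean embedding.
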