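# trophicweb

Quantitative analysis of plot-level host–parasitoid interaction networks in
tree-diversity experiments.

Cavity-nesting bees and wasps (the *hosts*) and the parasitoids that destroy
their brood cells form small bipartite networks that can be censused per
plot with trap nests. In a designed tree-diversity gradient, the central
questions are whether those networks are structured beyond chance, whether
host and parasitoid communities track each other (taxonomically and
phylogenetically), and how tree diversity and stand covariates shape
network architecture. `trophicweb` implements that complete analysis as a
reusable Python library, together with a synthetic-data generator that
emulates a two-site experiment (85 analysis plots, tree richness gradient
1–24, ~56 host and ~50 parasitoid species) so every stage can be validated
end to end against known ground truth.

## What it computes

**Network indices** for an I×J count matrix with cell totals `A_i`, `A_j`
and grand total `m` (`p_ij = n_ij / m`, `H` in bits):

- generality `G = Σ_j (A_j/m)·2^{H_j}` — effective host species per parasitoid
- vulnerability `V = Σ_i (A_i/m)·2^{H_i}` — effective parasitoid species per host
- linkage density `Lq = (G + V)/2`
- interaction evenness `E = −Σ p_ij ln p_ij / ln(I·J)`
- robustness — area under the parasitoid survival curve as hosts are removed
  in random order (computed exactly from the hypergeometric expectation of
  the extinction curve)

**Inference and multivariate stages**

- Patefield fixed-margin null models (exact sequential hypergeometric
  sampling) with two-sided permutation p-values and z-scores per index
- ParaFit test of host–parasitoid cophylogenetic congruence (principal
  coordinates, fourth-corner statistic, row-wise permutation null)
- abundance-weighted community phylogenetics: MPD, MNTD, Rao's Q,
  between-community MPD matrices
- Morisita–Horn dissimilarities, 2-D non-metric MDS (Kruskal stress-1,
  PCoA + random restarts, principal-components rotation), environmental
  vector fitting, Mantel tests, PERMANOVA with marginal term tests
- standardized OLS of each index on plot predictors with site interactions,
  collinearity (VIF) checks and AICc backward simplification

## Worked example

```python
from trophicweb import InteractionMatrix, all_indices

web = InteractionMatrix(
    "demo-plot",
    host_labels=["Anterhynchium flavomarginatum", "Deuterageniella sp1"],
    parasitoid_labels=["Chrysis principalis", "Amobia sp1"],
    counts=[[2, 0], [1, 1]],
)
for name, value in all_indices(web).as_dict().items():
    print(f"{name:22s} {value:.4f}")
```

```
generality             1.6674
vulnerability          1.5000
linkage_density        1.5837
interaction_evenness   0.7500
robustness             0.6250
```

A parasitoid in this web attacks 1.67 effective host species and each host
suffers 1.5 effective parasitoid species; interactions use 75% of the
maximum possible evenness, and the parasitoid level retains on average
62.5% of the area under its survival curve as hosts are removed at random.

Testing a well-sampled simulated plot against its Patefield null
(`examples/null_models.py`):

```
plot plot-039: 29 hosts x 20 parasitoids, m=159
generality             observed=  1.978  null mean=  6.435  z=-12.89  p=0.002
vulnerability          observed=  1.958  null mean=  7.205  z=-13.88  p=0.002
linkage_density        observed=  1.968  null mean=  6.820  z=-13.86  p=0.002
interaction_evenness   observed=  0.498  null mean=  0.679  z=-29.29  p=0.002
robustness             observed=  0.675  null mean=  0.774  z=-12.95  p=0.002
```

The observed web is far more specialized than fixed-margin chance: each
parasitoid concentrates on ~2 effective hosts where random reassortment of
the same totals would spread it over ~6.

The `examples/` directory has one short script per capability (indices,
null models, community phylogenetics, NMDS + envfit, ParaFit, linear
models, full pipeline). A thin CLI mirrors the stages:

```bash
trophicweb simulate --seed 0 --out data/
trophicweb metrics  --data data/ --out indices.csv
trophicweb all      --out results/ --seed 0
```

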