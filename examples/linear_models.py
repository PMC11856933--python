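"""Standardized linear models of network indices with AICc simplification.

Each index is regressed on standardized plot predictors (log2 tree
richness, canopy cover, terrain covariates, site); backward elimination
drops nonsignificant terms whose removal lowers AICc.
"""

from trophicweb.pipeline import network_metrics_table, regression_models, tree_community_metrics
from trophicweb.simulate import SimulationConfig, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=4))
indices = network_metrics_table(dataset)
tree_metrics = tree_community_metrics(dataset)

fits = regression_models(dataset, indices, tree_metrics)
fit = fits["linkage_density"]["primary"]
print(f"linkage density ~ {' + '.join(fit.terms) or '1'}   (AICc={fit.aicc:.1f}, R2={fit.r_squared:.2f})")
print(fit.coefficients.round(3))

# Standardized estimates are directly comparable across predictors; the
# retained richness term with a positive estimate reproduces the
# simulated positive effect of tree diversity on network complexity.
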