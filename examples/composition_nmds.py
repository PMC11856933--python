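"""Ordinate host community composition and fit environmental vectors.

Morisita-Horn dissimilarities between plots feed a 2-D non-metric MDS;
standardized plot covariates are then regressed on the axis scores and
their significance assessed by permutation (the envfit procedure).
"""

import numpy as np
import pandas as pd

from trophicweb import AnalysisConfig, envfit, morisita_horn_matrix, nmds
from trophicweb.simulate import SimulationConfig, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=2))
hosts = dataset.host_abundance.to_frame()
dissim = morisita_horn_matrix(hosts)

config = AnalysisConfig(random_seed=2, nmds_restarts=10, n_perm_ordination=999)
ordination = nmds(dissim, config)
print(f"2-D NMDS stress = {ordination.stress:.3f} (converged: {ordination.converged})")

cov = dataset.covariates
env = pd.DataFrame(
    {
        "log2_richness": np.log2(cov["tree_species_richness"].astype(float)),
        "canopy_cover": cov["canopy_cover"],
        "elevation": cov["elevation"],
        "eastness": cov["eastness"],
    },
    index=cov.index,
)
for fit in envfit(ordination, env, config):
    arrow = f"({fit.direction[0]:+.2f}, {fit.direction[1]:+.2f})"
    print(f"{fit.variable:14s} R2={fit.r_squared:.3f}  p={fit.p_value:.3f}  arrow={arrow}")

# An arrow shows the direction in ordination space along which the
# variable increases; R2 is the strength of that alignment and p its
# permutation significance (999 permutations).
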