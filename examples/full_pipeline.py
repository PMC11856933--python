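"""Run every analysis stage end to end on a synthetic study.

Writes all stage outputs (CSV) and a JSON manifest to ./pipeline_results;
stochastic stages run at reduced sizes so the example finishes in about a
minute.  Equivalent shell command:

    trophicweb all --out pipeline_results --seed 0 --n-null 500
"""

import json

from trophicweb import AnalysisConfig
from trophicweb.pipeline import run_all

config = AnalysisConfig(
    random_seed=0, n_perm_ordination=499, n_perm_parafit=999, nmds_restarts=5
)
manifest = run_all(config, out_dir="pipeline_results", n_null=500)
manifest.pop("_objects")
print(json.dumps(manifest["stages"], indent=2, default=float))

# The manifest records, per stage, the plot counts, per-index counts of
# plots departing from the Patefield null, NMDS stresses, the ParaFit
# p-value, and the simplified model structure per network index.
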