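"""Check how stable the clusters are to prior and threshold choices.

Re-runs the clustering over the default grid of conditional colocalization
priors pc in {0.05, 0.02, 0.01, 0.005} and thresholds
P_R* = P_A* in {0.5, 0.6, 0.7}, then reports how often each trait pair
lands in the same cluster. Frequencies near 1 mark robust groupings;
intermediate values flag prior-sensitive traits. A heatmap and TSV are
written next to this script's working directory.
"""

import tempfile
from pathlib import Path

import numpy as np

from multicoloc import builtin_scenario, sensitivity_grid, simulate_region
from multicoloc.sensitivity import export_heatmap

scenario = builtin_scenario("iii", Q=150)
region, truth = simulate_region(scenario, rng=np.random.default_rng(23))
result = sensitivity_grid(region)

print("planted clusters:", [sorted(g) for g in truth.partition])
print("co-clustering frequency across the 12 grid cells:")
print(result.to_frame().round(2).to_string())

out = Path(tempfile.mkdtemp()) / "sensitivity.png"
img, tsv = export_heatmap(result, out)
print(f"heatmap: {img}\nmatrix : {tsv}")
# Dark blocks in the heatmap that persist across the grid correspond to
# trait clusters that do not depend on the exact prior specification.
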