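"""Run the complete workflow on a simulated study and inspect the manifest.

Simulates the default-scale study (67 annotated metabolites, 47 unknown
biological compounds, 50 background decoys, five conditions x 3
replicates), then runs annotation -> credentialing -> pairing/quantification
-> statistics and prints the stage counts.  The same thing is available
from the shell as `isodiel run config.yaml --out results/`.
"""

import json

import numpy as np

from isodiel import run_pipeline

result = run_pipeline({"seed": 0}, "scratch/example_run")
print(json.dumps(result.manifest["counts"], indent=2))
print("PC1/PC2 explained variance:",
      [round(v, 3) for v in result.manifest["pca_explained_variance_ratio"][:2]])
print(f"peak growth rate: {np.nanmax(result.mu_series.mu):.3f} /h")
# Expect: all 114 planted biological compounds credentialed and paired in
# every sample, 67 matrix rows annotated, ~92 rows ANOVA-significant (the
# planted diurnal classes), and a peak mu near 0.16 /h.
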