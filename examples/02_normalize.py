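"""Harmonize a multi-plex experiment: impute, exclude, SL/TMM/log2/ComBat.

Runs the full normalization stack on a batch-confounded simulation and
shows that plex structure dominates the raw data but not the output.
"""

import numpy as np

from gxeprot import (
    TruthParams, generate_design, normalize_pipeline, one_way_anova,
    partial_epsilon_squared, run_pca, simulate_intensities,
)

design = generate_design(seed=2)
matrix, _ = simulate_intensities(
    design, TruthParams.batch_only(n_proteins=400), seed=2
)

norm, report = normalize_pipeline(matrix, design)
print("steps:", " -> ".join(norm.provenance))
print(f"detected {report.n_detected}, imputed {report.n_imputed}, "
      f"excluded {report.n_excluded}, retained {report.n_retained}")

for label, data in [("raw log2", np.log2(matrix)), ("normalized", norm.data)]:
    pca = run_pca(data)
    F, df1, df2 = one_way_anova(pca.scores["PC1"], design["plex"])
    eps = partial_epsilon_squared(F, df1, df2).epsilon2
    print(f"{label:>10}: plex explains eps^2 = {eps:.3f} of PC1")
# Before correction, PC1 is essentially a plex axis (eps^2 near 1);
# after the pipeline the batch signal on PC1 is negligible (< 0.06).
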