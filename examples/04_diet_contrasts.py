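"""Per-protein diet contrasts with FDR control and directional summaries.

Simulates a proteome where isolines respond to diet in opposite
directions (G x E) with no consistent across-isoline diet effect, fits
the mixed-model high-low contrast per protein, and summarizes
direction of change by protein class.
"""

import numpy as np
import pandas as pd

from gxeprot import (
    TruthParams, class_mean_logfc, directional_bias, fit_contrasts,
    generate_design, simulate_intensities,
)

design = generate_design(seed=4)
params = TruthParams.diet_null(n_proteins=400, batch_sd=0.0, loading_sd=0.0)
matrix, truth = simulate_intensities(design, params, seed=4)

classes = pd.Series(
    ["SFP" if i % 3 == 0 else "SpP" for i in range(len(matrix))],
    index=matrix.index,
)
result = fit_contrasts(np.log2(matrix), design, classes=classes)
table = result.table

print(f"proteins fitted:        {len(table)}")
print(f"p < 0.05 before FDR:    {(table['p'] < 0.05).sum()}")
print(f"q < 0.05 after FDR:     {(table['q'] < 0.05).sum()}")
print(f"mean logFC, SFP class:  {class_mean_logfc(result, 'SFP'):+.3f}")
print(f"mean logFC, SpP class:  {class_mean_logfc(result, 'SpP'):+.3f}")

bias = directional_bias(result, classes=("SFP", "SpP"))
print(f"direction table (down/up per class):\n{bias.counts}")
print(f"chi2_1 = {bias.chi2:.2f}, p = {bias.p:.3f}")
# A handful of proteins pass p < 0.05 by chance but none survive
# Benjamini-Hochberg correction, and the two classes do not differ in
# direction of change - the study's reported outcome for the diet axis.
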