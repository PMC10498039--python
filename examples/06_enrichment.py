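"""Rank-based gene-set enrichment and protein-type contribution tests.

Ranks proteins by their diet-contrast t statistics, runs the weighted
running-sum enrichment with a permutation null against synthetic gene
sets (one planted among high-diet responders), and tests whether one
protein type dominates PC1 contributions.
"""

import numpy as np
import pandas as pd

from gxeprot import (
    TruthParams, contribution_enrichment, fit_contrasts, generate_design,
    gsea, normalize_pipeline, pc_contributions, run_pca, simulate_intensities,
)

design = generate_design(seed=6)
n_prot = 300
effects = np.zeros(n_prot)
effects[:25] = 0.4  # a planted set of high-diet responders
params = TruthParams.null(n_proteins=n_prot, batch_sd=0.0, loading_sd=0.0,
                          diet_effects=tuple(effects))
matrix, _ = simulate_intensities(design, params, seed=6)
contrasts = fit_contrasts(np.log2(matrix), design)

ranked = contrasts.table["t"]
gene_sets = {
    "high_diet_responders": set(matrix.index[:25]),
    "random_set": set(matrix.index[100:140]),
}
res = gsea(ranked, gene_sets, weight=1.0, n_perm=1000, seed=6)
print(res.table[["es", "nes", "size", "p", "q"]].round(4))
# The planted set has a large positive enrichment score (leading on the
# high-diet side) and survives BH correction; the random set does not.

norm, _ = normalize_pipeline(matrix, design)
pca = run_pca(norm.data)
contrib = pc_contributions(pca, "PC1")["contribution"]
type_ind = pd.Series((np.arange(len(contrib)) < 150).astype(int),
                     index=contrib.index)
te = contribution_enrichment(contrib, type_ind)
print(f"\ncontribution difference: beta = {te.beta:+.4f} +/- {te.se:.4f}, "
      f"t_{te.df} = {te.t:.2f}, p = {te.p:.3f}")
# beta is the mean PC1-contribution difference between the two protein
# types; the type containing the planted diet responders contributes
# significantly more to PC1, the analysis used for SpP/SFP enrichment
# among component drivers.
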