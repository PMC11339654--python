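"""Genetic offset: how far is a population's home environment from a
reference environment, weighted by gene-environment associations.

A PCA of 19 bioclimatic covariates gives per-population environmental
scores e_j; per-SNP regressions of allele frequencies on the scores give
the coefficient matrix B; the offset GO_j = (1/n_snp) d'B'Bd with
d = e_j - e_ref is read as expected maladaptation of moving from
environment j to the reference.  Here the truth is simulated, so the
estimate can be checked against it.
"""

import numpy as np
from scipy.stats import spearmanr

from feralpop import offset, simdata

design, truth, covariates = simdata.generate_environment(
    n_pops=32, n_pcs=7, effect_scale=0.3, seed=3, n_snps=5000
)
print(f"PCA of {covariates.shape[1]} covariates over "
      f"{covariates.shape[0]} populations: {design.n_pcs} PCs retained, "
      f"{design.variance_explained.sum():.1%} of variance explained")

b_hat = offset.estimate_gea_coefficients(truth.pop_freqs, design.scores)
aff = truth.affected
corr = np.corrcoef(b_hat[aff].ravel(), truth.b_true[aff].ravel())[0, 1]
print(f"GEA coefficient recovery at the {aff.sum()} effect-carrying SNPs: "
      f"r = {corr:.3f}")

table = offset.offset_table(design, b_hat, ref_pop=design.pop_names[0])
table_t = table.sort_values("go")
print("GO and plain environmental distance delta relative to "
      f"{design.pop_names[0]}:")
print(table_t.tail(3).to_string(index=False, float_format="%.4f"))
go_true = [offset.genetic_offset(truth.b_true, e, design.scores[0])
           for e in design.scores]
rho = spearmanr(table["go"], go_true).statistic
print(f"rank agreement with the true-coefficient offsets: "
      f"Spearman rho = {rho:.3f} — GO orders environments by expected "
      f"maladaptation, not just by raw climate distance")
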