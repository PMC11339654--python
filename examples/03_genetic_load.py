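"""Genetic-load statistics by functional class.

Per individual: NS/S heterozygote ratio and masked vs realized load for
deleterious classes.  Between populations: the RX/Y statistic — the ratio
of the probability of sampling a derived allele in X and not in Y over
the reverse — standardized by intergenic variants; values above 1 mean
relaxed purifying selection in X.
"""

import numpy as np

import feralpop as fp
from feralpop import glfreq, load, simdata
from feralpop.panels import derived_is_alt, polarized_mask

cfg = fp.SimConfig(n_sites=4000, n_chromosomes=4, chrom_length=4e6,
                   source_size=1500, t_divergence=300, seed=9)
hap, truth, variants = fp.simulate_cohort(cfg)
gpanel = simdata.emit_sequencing_data(hap, cfg)

ns_s = load.ns_s_het_ratio(gpanel, variants)
print("mean NS/S het ratio per population:")
for pop in ("TARGET", "SRC1", "SRC2"):
    idx = gpanel.pops == pop
    print(f"  {pop}: {np.nanmean(ns_s[idx]):.3f}")

mr = load.masked_realized_load(gpanel, variants, "ns_deleterious")
print(f"deleterious missense, target individuals: masked "
      f"{mr['masked'][gpanel.pops == 'TARGET'].mean():.3f}, realized "
      f"{mr['realized'][gpanel.pops == 'TARGET'].mean():.3f} "
      f"(heterozygous burden is hidden from selection; homozygous-derived "
      f"burden is expressed)")

pol = polarized_mask(variants)
alt_der = derived_is_alt(variants)
fx = glfreq.derived_frequencies(
    glfreq.em_allele_frequencies(gpanel, "TARGET"), alt_der)
fy = glfreq.derived_frequencies(
    glfreq.em_allele_frequencies(gpanel, "SRC1"), alt_der)
cls = (variants["vclass"] == "ns_deleterious").to_numpy() & pol
ref = (variants["vclass"] == "intergenic").to_numpy() & pol
res = load.rxy(fx, fy, cls, ref, n_blocks=20)
print(f"standardized R_TARGET/SRC1 (deleterious missense): "
      f"{res.standardized:.3f} [95% CI {res.ci_low:.3f}, {res.ci_high:.3f}]"
      f" — >1 indicates relaxed purifying selection in the founder "
      f"population")
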