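# Methods

This note documents the models and estimators implemented in `feralpop`,
the choices made where several conventions exist, and what the synthetic
data generator does and does not emulate.

## The synthetic cohort generator

`simdata.simulate_cohort` produces a three-population cohort: a target
founded by `n_founders` diploids (default 5) `t_bottleneck` generations ago
(default 22) as a mixture of two source populations
(`admixture_fraction` from source 1, default 0.75), expanding
exponentially to `expansion_size` (default 500) by sampling time; the two
sources (default 5,000 diploids each) split `t_divergence` generations ago.
Default sampling is 8 diploids per population, mirroring a small
whole-genome panel.

The engine is a hybrid:

- **Neutral classes** (selection coefficient s = 0; by default intergenic
  and synonymous sites) come from an msprime coalescent simulation of the
  demography above, one independent ancestry per chromosome, with binary
  mutations and a uniform recombination rate of 1 cM/Mb (`map_rate`).
  These sites carry realistic linkage disequilibrium and genealogical
  correlation — essential for the EHH scan and for block-jackknife
  behaviour.
- **Selected classes** (s < 0; tolerated missense s = −0.001, deleterious
  missense s = −0.01 with h = 0.25, loss-of-function s = −0.05 with
  h = 0.1) are evolved forward in time site by site: initial derived
  frequencies drawn from the neutral 1/i spectrum, then per-generation
  deterministic viability selection (fitnesses 1 : 1+hs : 1+s) followed by
  binomial resampling of 2N gametes, through the split, the founder
  draw (2·`n_founders` gametes from the admixed pool) and the expansion.
  These sites are in linkage equilibrium and are interleaved at random
  positions.  A coalescent engine cannot carry selection cheaply; a
  linked forward simulation of whole chromosomes would dwarf the rest of
  the package.  Consequence: selection-scan analyses should use neutral
  (fully coalescent) configurations, and load statistics — which are
  per-site — are unaffected.

Per-class default selection strengths are conventional orders of magnitude
for missense and LoF variation in livestock-sized genomes; class
proportions (70% intergenic, 10% synonymous, 8% + 8% missense, 4% LoF)
follow the makeup of a WGS SNP panel after standard filtering.

Ground truth (`SimTruth`) records per-site class labels, per-population
sample derived-allele frequencies, founder frequencies for
forward-simulated sites, and expected per-individual source-1 ancestry
(the admixture fraction for target individuals; local-ancestry tracts are
not tracked).

About 30% of sites present the derived allele as the VCF REF so that
polarisation logic is exercised; the annotation table carries the
ancestral base.

**What the generator does not emulate:** within-target substructure (the
target is panmictic post-founding), sex chromosomes and mitochondria,
recombination-map heterogeneity, structural variants, reference bias,
indel/alignment artefacts, and linkage for selected sites.  Tests passing
on these cohorts validate the estimators' statistical behaviour, not
robustness to real-data artefacts.

`emit_sequencing_data` models sequencing as: depth ~ Poisson(`mean_depth`,
default 10×); each read reports the true allele with probability
1 − `error_rate` (default 0.002, a post-filtering short-read scale);
genotype likelihoods from the symmetric-error binomial model (alt-read
probability e, ½, 1−e for the three genotypes), Phred-scaled, rounded to
integers, capped at 255 and normalised so the best genotype has PL 0.
Zero-depth entries get a flat triple and a missing call.

`generate_environment` builds a latent low-rank environmental covariate
matrix (19 "bioclimatic" columns), retains its PCA, and makes population
allele frequencies deviate from a uniform baseline by
`B_true · scores_std` at a 10% subset of SNPs plus N(0, 0.02) noise.
`effect_scale` (SD of non-zero B entries) is the association strength; 0
gives an exact null.

## Allele frequencies and the probabilistic SFS

The EM estimator treats the de-Phred-ed, renormalised PL triples as
genotype likelihoods, with Hardy–Weinberg priors given the current
frequency.  Initialisation is the GL-weighted naive dosage mean;
convergence is |Δp̂| < 10⁻⁶ with at most 100 iterations (the marginal
likelihood is non-decreasing every step; near p̂ → 0/1 convergence is slow
and the cap may bind, which matters only in the last decimal).  Missing
individuals are dropped per site, not imputed.

Thresholds are strict: segregating means 0.001 < p̂ < 0.999; fixed-derived
means derived p̂ > 0.999.  The fixed-site extrapolation multiplies the
proportion of fixed-derived among *polarised* sites by the total site
count; a flag (`polarized_only_denominator`) switches the denominator to
all sites.

The SFS path multiplies per-individual generating polynomials
`GP₀ + GP₁z + GP₂z²`; the coefficient of zᵏ is P(k derived copies).  This
equals the brute-force sum over 3ⁿ configurations (asserted to 10⁻¹² for
n = 3 and n = 8 in the tests) at O(n²) per site instead of O(3ⁿ).  Sites
enter only if polarised and fully called in the population; k = 0 and
k = 2n are excluded from the reported spectrum.

Expected heterozygosity is the across-site mean of 2p̂(1−p̂)·2n/(2n−1).

## F-statistics and kinship

Weir–Cockerham variance components a, b, c are computed per site and
combined as ratios of sums (the weighted combination; the source estimator
leaves multi-population weighting open).  Per-population F_IS uses the
single-population reduction b = n/(n−1)·[p̂(1−p̂) − h(2n−1)/(4n)], c = h/2,
F_IS = b/(b+c).  Sites monomorphic across the analysed populations are
excluded; populations need ≥ 2 diploids.

f-statistics use the unbiased allele-count estimators: with
ĥ = p̂(1−p̂)·n/(n−1) on n haploid calls,
f2 = (p̂_A−p̂_B)² − ĥ_A/n_A − ĥ_B/n_B, f3(A;B,C) subtracts only ĥ_A/n_A,
f4 needs no correction.  The f3 admixture call is Z < −1.65 (one-sided
95%).  Note the corrections assume independent sampling: f2 between two
*disjoint* samples of one population is unbiased at 0, but duplicated
individuals violate the premise.  The F4-ratio α = f4(num)/f4(den) requires
quadruplets in which the denominator captures a shared internal branch;
with an uninformative denominator the ratio is ill-conditioned (the
recovery experiments use a reference population that is a sister of source
1).

All SEs are delete-one block jackknives over contiguous blocks of 250
SNPs in genome order (final short block kept); CI = estimate ± 1.96·SE,
Z = estimate/SE.

ASD uses the "random allele mismatch" dialect: per-site distance
x(1−y) + (1−x)y with x, y the half-dosages, i.e. 0/0.5/1 for identical
homozygotes / one het involved (including het–het) / opposite homozygotes.

Kinship is the KING-robust within-pair estimator
φ = (N_het,het − 2·N_opp-hom)/(N_het(i) + N_het(j)) over co-called sites
(warning below 1,000).  Degree classes use the powers-of-two bounds
2^(−(2d+3)/2), closed on the lower end; φ ≥ 2^(−3/2) is labelled
`duplicate` so that every finite φ maps to exactly one class.  IBD-segment
sharing, which can upgrade degree calls, is not implemented.

## Genetic load

Heterozygote/homozygote counts are expectations over genotype
probabilities by default (`hard_calls=True` switches to calls).  Masked
and realized load are per-individual proportions over the individual's
*called* sites of the class, requiring polarisation; the orientation flips
where the derived allele is REF.  RX/Y jackknife blocks are built as 100
equal-SNP contiguous blocks separately on the class and normalizer site
lists and dropped jointly by index; remainder SNPs join the last block.
Whether to use EM or count frequencies as fX/fY is the caller's choice
(the pipeline uses EM).

## Genetic offset

`env_pca` centers and scales covariates, takes the SVD, and retains 7 PCs
by default (or the smallest count reaching a variance-explained
threshold); constant columns are dropped with a warning.  Projection of
new rows applies the training centering/scaling and loadings, so training
rows reproduce their scores exactly.

The GEA coefficient estimator is a per-SNP OLS (optional ridge; forced
ridge of 10⁻⁶ under collinearity) of population allele frequencies on the
*standardized* PC scores with an intercept.  This is a deliberate,
documented stand-in for a hierarchical population-structure-aware MCMC
model: it ignores the neutral covariance of populations, so its
correctness criterion is recovery of simulated truth (coefficient
correlation > 0.8 at effect-carrying SNPs; GO rank correlation > 0.9),
not equality with any particular external sampler.  Frequencies enter
raw; an arcsine-sqrt transform is available but off by default.

GO and δ follow the quadratic-form and normalised-Euclidean definitions
above; GO ≥ 0 always, GO = 0 iff B·d = 0, and GO ∝ δ² exactly when
BᵀB ∝ I.  `go_surface` evaluates GO per grid row after projection,
skipping rows with missing covariates; output is a plain table (no raster
dependency).

## EHH scan and local score

EHH at distance d from a focal allele is the probability that two random
carrier haplotypes are identical over the intervening markers (grouped
incrementally; Σ n_h(n_h−1)/(n(n−1))).  EHH at the focal SNP is 1 by
definition; an allele with < 2 carriers is undefined.  iHH integrates EHH
by the trapezoidal rule outward until it drops below 0.05, including the
bridging trapezoid to the first sub-cutoff marker.  iHS is
ln(iHH₁/iHH₀) with allele 1 the panel's alternate allele (no
polarisation, so the sign is a fixed but arbitrary convention),
standardized to mean 0, SD 1 in a single frequency bin over all SNPs with
MAF > 0.01.  Rsb contrasts integrated site-EHH (pairwise identity over
all haplotypes, normalised to 1 at the focal SNP) between populations,
standardized the same way; positive = longer homozygosity in X.

p-value scores use the normal-theory transforms (two-sided for iHS,
one-sided for Rsb) computed through `log_ndtr` for tail stability.  SNP
scores are p-score − ξ with ξ = 2 (so SNPs with p ≥ 10⁻² contribute
negatively).  The Lindley process accumulates them; an excursion runs
from the first SNP where L rises above 0 to the last SNP before it
returns to 0 (excursion-start convention; window bounds are those SNPs'
positions), with the leftmost argmax as peak.

The per-chromosome 1% threshold is Monte-Carlo by default: the 99th
percentile of the maximal excursion height over 1,000 random permutations
of the chromosome's scores (permutation preserves the score distribution
and breaks spatial arrangement; note it also breaks LD, making the
threshold mildly anticonservative on strongly autocorrelated score
tracks).  An analytic Gumbel-type mode solves E[e^{λX}] = 1 on the
empirical scores and sets the threshold from
P(M > x) ≈ 1 − exp(−n·e^{−λx}); the omitted Karlin–Dembo prefactor K < 1
makes this a conservative upper bound (typically a few tenths above the
MC threshold), so MC remains the default.  On i.i.d. standard-normal
statistics the MC machinery flags ~1% of chromosomes, verified over 200
replicates.

Nearest-gene annotation reports distance 0 for a peak inside a gene, else
the gap to the closer boundary in kb; equidistant genes are all reported
and flagged ambiguous.  Gene intervals are handled 0-based half-open
internally; VCF/peak positions are 1-based.

## Chronology

Calendar conversions round to the nearest whole year.  HBD classes follow
the exponential-length model: rate R_c ⇒ expected segment 1/R_c Morgans,
ancestors ≈ R_c/2 generations back; the default grid doubles from 2 to
8,192 (13 classes).  Fitting the HBD HMM itself is out of scope — only
the class-parameter arithmetic used to interpret such fits is provided.

## Pipeline and problem sizes

`pipeline.run_pipeline` chains simulate → freqs → load → fstats → kinship
→ offset → scan → chrono, writing one TSV per stage plus a summary whose
every number comes from a stage table.  Fixed seeds give byte-identical
outputs.  Defaults in tests and the acceptance script use desk-scale
cohorts — 2–4 chromosomes of 3–5 Mb, 1,500–4,000 sites, 8 diploids per
population, 10–40 replicates per experiment — chosen so the full suite
and the acceptance run each complete in minutes while leaving the
qualitative signatures (SFS flattening, RX/Y > 1 under relaxed selection,
F4-ratio coverage) clearly resolved.  Flattening comparisons need ≥ ~4
independent chromosome genealogies to be stable; with fewer, the
stochastic survival of founder lineages occasionally masks the signal.

## Known limitations

- Selected sites are unlinked; background-selection and hitchhiking
  effects on linked neutral diversity are absent.
- Local ancestry is not tracked; per-individual ancestry truth is the
  expected admixture fraction.
- The GEA stand-in ignores neutral population covariance and will
  overstate associations under strong shared drift.
- The analytic local-score threshold is a conservative bound, not an
  exact quantile.
- KING IBD-segment-based relationship upgrades are future work.
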