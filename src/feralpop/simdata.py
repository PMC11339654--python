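"""Synthetic cohorts with the statistical structure of an island founder
population.

The generator emulates a target population established by a handful of
founders of admixed origin (two source populations), followed by rapid
expansion — the demography under which all downstream statistics are
exercised.  It is a hybrid engine:

* neutral variant classes come from a coalescent simulation (msprime) of
  the three-population demography, so neutral sites carry realistic
  linkage disequilibrium and sample correlation structure;
* variant classes under purifying selection are evolved forward in time,
  site by site (linkage equilibrium), with Wright–Fisher resampling under
  genotype fitnesses 1, 1+hs, 1+s for the ancestral-homozygote,
  heterozygote and derived-homozygote.

Sequencing is emulated with Poisson read depths and a symmetric-error
binomial read model, producing Phred-scaled genotype likelihoods (PL)
normalised so the best genotype is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd
from scipy.stats import binom

from .panels import (
    MISSING,
    VARIANT_CLASSES,
    GenotypePanel,
    HaplotypePanel,
    variant_table,
)

_BASES = np.array(["A", "C", "G", "T"])

#: default per-class selection (s, h): neutral for intergenic/synonymous,
#: mildly deleterious tolerated missense, partially recessive deleterious
#: missense, strongly deleterious and recessive LoF
DEFAULT_SELECTION = {
    "intergenic": (0.0, 0.5),
    "synonymous": (0.0, 0.5),
    "ns_tolerated": (-0.001, 0.5),
    "ns_deleterious": (-0.01, 0.25),
    "lof": (-0.05, 0.1),
}

DEFAULT_PROPORTIONS = {
    "intergenic": 0.70,
    "synonymous": 0.10,
    "ns_tolerated": 0.08,
    "ns_deleterious": 0.08,
    "lof": 0.04,
}

POP_TARGET = "TARGET"
POP_SRC1 = "SRC1"
POP_SRC2 = "SRC2"


@dataclass
class SimConfig:
    """Scenario parameters for the founder-bottleneck cohort.

    Defaults mirror the studied island scenario: five founders 22
    generations before sampling, ~75% ancestry from source 1, rapid
    expansion, and a uniform 1 cM/Mb genetic map.
    """

    n_founders: int = 5
    admixture_fraction: float = 0.75
    t_bottleneck: int = 22
    t_divergence: int = 2000
    expansion_size: int = 500
    source_size: int = 5000
    n_per_pop: int = 8
    n_sites: int = 50_000
    n_chromosomes: int = 5
    chrom_length: float = 10e6
    mutation_rate: float = 1e-8
    selection: dict = field(default_factory=lambda: dict(DEFAULT_SELECTION))
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    mean_depth: float = 10.0
    error_rate: float = 0.002
    map_rate: float = 1.0  # cM per Mb
    seed: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.admixture_fraction <= 1.0:
            raise ValueError(
                "admixture_fraction must lie in [0, 1], got "
                f"{self.admixture_fraction}"
            )
        if self.n_founders < 2:
            raise ValueError(f"n_founders must be >= 2, got {self.n_founders}")
        props = self.class_proportions
        if set(props) - set(VARIANT_CLASSES):
            raise ValueError(f"unknown classes: {set(props) - set(VARIANT_CLASSES)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"class proportions must sum to 1, got {sum(props.values())}"
            )
        for cls in ("ns_deleterious", "lof"):
            s, _ = self.selection.get(cls, (0.0, 0.5))
            if s > 0:
                raise ValueError(
                    f"selection coefficient for deleterious class {cls!r} "
                    f"must be <= 0, got {s}"
                )
        if self.expansion_size < self.n_founders:
            raise ValueError("expansion_size must be >= n_founders")
        if self.t_bottleneck < 1 or self.t_divergence <= self.t_bottleneck:
            raise ValueError("need t_divergence > t_bottleneck >= 1")

    @property
    def recombination_rate(self) -> float:
        # cM/Mb -> crossover probability per bp per generation
        return self.map_rate * 1e-8


@dataclass
class SimTruth:
    """Simulator ground truth for recovery tests."""

    site_class: np.ndarray
    derived_freqs: dict  # pop -> per-site sample derived-allele frequency
    ancestry: pd.Series  # per-individual expected source-1 ancestry dosage
    founder_freqs: np.ndarray  # derived freq at founding (NaN for coalescent sites)
    admixture_fraction: float
    seed: int


# ---------------------------------------------------------------------------
# Forward Wright–Fisher engine (per-site, vectorised across sites)
# ---------------------------------------------------------------------------


def selection_update(p: np.ndarray, s: float, h: float) -> np.ndarray:
    """Deterministic change in derived-allele frequency after one
    generation of viability selection (fitnesses 1 : 1+hs : 1+s)."""
    q = 1.0 - p
    w_bar = q * q + 2 * p * q * (1 + h * s) + p * p * (1 + s)
    return (p * p * (1 + s) + p * q * (1 + h * s)) / w_bar


def wright_fisher_frequencies(
    p0: np.ndarray,
    pop_sizes: np.ndarray,
    s: float,
    h: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve derived-allele frequencies through successive generations.

    ``pop_sizes`` lists the diploid population size at each generation;
    each step applies selection deterministically then binomial drift
    sampling of 2N gametes.
    """
    p = np.asarray(p0, dtype=float).copy()
    for n_dip in pop_sizes:
        p = selection_update(p, s, h) if s != 0.0 else p
        p = rng.binomial(int(2 * n_dip), p) / (2.0 * n_dip)
    return p


def _neutral_sfs_start(n_sites: int, two_n: int, rng) -> np.ndarray:
    """Initial derived frequencies drawn from the neutral 1/i spectrum."""
    i = np.arange(1, two_n)
    w = 1.0 / i
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / two_n


def _expansion_sizes(cfg: SimConfig) -> np.ndarray:
    """Exponential growth schedule from n_founders to expansion_size over
    the bottleneck generations."""
    g = np.arange(1, cfg.t_bottleneck + 1)
    sizes = cfg.n_founders * (cfg.expansion_size / cfg.n_founders) ** (
        g / cfg.t_bottleneck
    )
    return np.maximum(np.round(sizes).astype(int), 2)


def _forward_selected_sites(cfg: SimConfig, n_by_class: dict, rng):
    """Forward-simulate selected classes; returns per-site derived
    frequencies in each population plus founder frequencies and labels."""
    labels, p_t, p_1, p_2, p_found = [], [], [], [], []
    for cls, n_cls in n_by_class.items():
        if n_cls == 0:
            continue
        s, h = cfg.selection[cls]
        p0 = _neutral_sfs_start(n_cls, 2 * cfg.source_size, rng)
        # sources split at t_divergence and evolve independently until the
        # founding time, t_bottleneck generations before sampling
        pre = np.full(cfg.t_divergence - cfg.t_bottleneck, cfg.source_size)
        p1_f = wright_fisher_frequencies(p0, pre, s, h, rng)
        p2_f = wright_fisher_frequencies(p0, pre, s, h, rng)
        # founders draw 2*n_founders gametes from the admixed gene pool
        pool = (
            cfg.admixture_fraction * p1_f
            + (1 - cfg.admixture_fraction) * p2_f
        )
        pf = rng.binomial(2 * cfg.n_founders, pool) / (2.0 * cfg.n_founders)
        tail = np.full(cfg.t_bottleneck, cfg.source_size)
        p1 = wright_fisher_frequencies(p1_f, tail, s, h, rng)
        p2 = wright_fisher_frequencies(p2_f, tail, s, h, rng)
        pt = wright_fisher_frequencies(pf, _expansion_sizes(cfg), s, h, rng)
        labels.extend([cls] * n_cls)
        p_t.append(pt)
        p_1.append(p1)
        p_2.append(p2)
        p_found.append(pf)
    if not labels:
        return np.array([], dtype=object), {}, np.array([])
    freqs = {
        POP_TARGET: np.concatenate(p_t),
        POP_SRC1: np.concatenate(p_1),
        POP_SRC2: np.concatenate(p_2),
    }
    return np.array(labels, dtype=object), freqs, np.concatenate(p_found)


# ---------------------------------------------------------------------------
# Coalescent demography for neutral classes
# ---------------------------------------------------------------------------


def _demography(cfg: SimConfig) -> msprime.Demography:
    dem = msprime.Demography()
    growth = np.log(cfg.expansion_size / cfg.n_founders) / cfg.t_bottleneck
    dem.add_population(
        name=POP_TARGET, initial_size=cfg.expansion_size, growth_rate=growth
    )
    dem.add_population(name=POP_SRC1, initial_size=cfg.source_size)
    dem.add_population(name=POP_SRC2, initial_size=cfg.source_size)
    dem.add_population(name="ANC", initial_size=cfg.source_size)
    dem.add_admixture(
        time=cfg.t_bottleneck,
        derived=POP_TARGET,
        ancestral=[POP_SRC1, POP_SRC2],
        proportions=[cfg.admixture_fraction, 1 - cfg.admixture_fraction],
    )
    dem.add_population_split(
        time=cfg.t_divergence, derived=[POP_SRC1, POP_SRC2], ancestral="ANC"
    )
    return dem


def _coalescent_haplotypes(cfg: SimConfig, rng):
    """Simulate neutral haplotypes chromosome by chromosome.

    Returns (chrom labels, positions, hap matrix with derived allele = 1).
    """
    dem = _demography(cfg)
    chroms, positions, mats = [], [], []
    for c in range(cfg.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples={POP_TARGET: cfg.n_per_pop, POP_SRC1: cfg.n_per_pop,
                     POP_SRC2: cfg.n_per_pop},
            demography=dem,
            sequence_length=cfg.chrom_length,
            recombination_rate=cfg.recombination_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=cfg.mutation_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
        )
        keep_pos, rows = [], []
        for var in mts.variants():
            if len(var.alleles) != 2:
                continue
            keep_pos.append(int(var.site.position) + 1)
            rows.append(var.genotypes.astype(np.int8))
        if not rows:
            continue
        pos = np.asarray(keep_pos)
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        chroms.extend([str(c + 1)] * int(uniq.sum()))
        positions.append(pos[uniq])
        mats.append(np.asarray(rows)[uniq])
    if not mats:
        raise RuntimeError("coalescent simulation produced no variable sites")
    return (
        np.asarray(chroms, dtype=object),
        np.concatenate(positions),
        np.concatenate(mats, axis=0),
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimConfig) -> tuple[HaplotypePanel, SimTruth, pd.DataFrame]:
    """Generate the phased cohort: target population plus the two
    unadmixed source control populations.

    Returns (haplotype panel, ground truth, variant annotation table).
    Neutral classes (s = 0) are drawn from the coalescent simulation and
    carry linkage; selected classes are forward-simulated per site in
    linkage equilibrium and interleaved at random positions.  Reproducible
    for a fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_ind = 3 * cfg.n_per_pop

    neutral_classes = [c for c, p in cfg.class_proportions.items()
                       if cfg.selection.get(c, (0.0, 0.5))[0] == 0.0 and p > 0]
    selected_classes = [c for c, p in cfg.class_proportions.items()
                        if cfg.selection.get(c, (0.0, 0.5))[0] != 0.0 and p > 0]

    chrom_c, pos_c, hap_c = _coalescent_haplotypes(cfg, rng)

    n_sel_by_class = {
        c: int(round(cfg.class_proportions[c] * cfg.n_sites))
        for c in selected_classes
    }
    n_sel = sum(n_sel_by_class.values())
    n_neutral_target = max(cfg.n_sites - n_sel, 0)
    if hap_c.shape[0] > n_neutral_target:
        keep = np.sort(
            rng.choice(hap_c.shape[0], size=n_neutral_target, replace=False)
        )
        chrom_c, pos_c, hap_c = chrom_c[keep], pos_c[keep], hap_c[keep]

    w = np.array([cfg.class_proportions[c] for c in neutral_classes], dtype=float)
    labels_c = rng.choice(
        np.array(neutral_classes, dtype=object), size=hap_c.shape[0], p=w / w.sum()
    )

    labels_s, freqs_s, founder_s = _forward_selected_sites(cfg, n_sel_by_class, rng)
    n_sel = len(labels_s)
    if n_sel:
        chrom_s = rng.integers(1, cfg.n_chromosomes + 1, size=n_sel).astype(str)
        pos_s = rng.integers(1, int(cfg.chrom_length), size=n_sel)
        hap_s = np.empty((n_sel, 2 * n_ind), dtype=np.int8)
        for pop, sl in (
            (POP_TARGET, slice(0, 2 * cfg.n_per_pop)),
            (POP_SRC1, slice(2 * cfg.n_per_pop, 4 * cfg.n_per_pop)),
            (POP_SRC2, slice(4 * cfg.n_per_pop, 6 * cfg.n_per_pop)),
        ):
            p = freqs_s[pop]
            hap_s[:, sl] = rng.binomial(
                1, p[:, None], size=(n_sel, sl.stop - sl.start)
            )
        variable = (hap_s.sum(axis=1) > 0) & (hap_s.sum(axis=1) < 2 * n_ind)
        chrom_s, pos_s = chrom_s[variable], pos_s[variable]
        hap_s, labels_s = hap_s[variable], labels_s[variable]
        founder_s = founder_s[variable]

        chrom = np.concatenate([chrom_c, chrom_s])
        pos = np.concatenate([pos_c, pos_s])
        hap = np.concatenate([hap_c, hap_s], axis=0)
        labels = np.concatenate([labels_c, labels_s])
        founder = np.concatenate(
            [np.full(len(labels_c), np.nan), founder_s]
        )
    else:
        chrom, pos, hap, labels = chrom_c, pos_c, hap_c, labels_c
        founder = np.full(len(labels_c), np.nan)

    order = np.lexsort((pos, chrom.astype(int)))
    chrom, pos, hap, labels, founder = (
        chrom[order], pos[order], hap[order], labels[order], founder[order]
    )
    # drop rare position collisions between coalescent and interleaved sites
    same = (chrom[1:] == chrom[:-1]) & (pos[1:] == pos[:-1])
    keep = np.concatenate([[True], ~same])
    chrom, pos, hap, labels, founder = (
        chrom[keep], pos[keep], hap[keep], labels[keep], founder[keep]
    )

    # ref/alt encoding: internally allele 1 is the derived allele; a random
    # 30% of sites present the derived allele as REF so that polarisation
    # is non-trivial downstream
    ref_b = rng.integers(0, 4, size=len(pos))
    alt_b = (ref_b + rng.integers(1, 4, size=len(pos))) % 4
    alt_is_derived = rng.random(len(pos)) < 0.7
    hap_enc = np.where(alt_is_derived[:, None], hap, 1 - hap).astype(np.int8)
    ancestral = np.where(alt_is_derived, _BASES[ref_b], _BASES[alt_b])

    samples = (
        [f"TAR_{i:02d}" for i in range(cfg.n_per_pop)]
        + [f"SR1_{i:02d}" for i in range(cfg.n_per_pop)]
        + [f"SR2_{i:02d}" for i in range(cfg.n_per_pop)]
    )
    pops = np.array(
        [POP_TARGET] * cfg.n_per_pop
        + [POP_SRC1] * cfg.n_per_pop
        + [POP_SRC2] * cfg.n_per_pop
    )
    cm = pos / 1e6 * cfg.map_rate
    panel = HaplotypePanel(
        chrom=chrom, pos=pos, cm=cm, hap=hap_enc, samples=samples, pops=pops
    )

    derived = {}
    for pop, sl in (
        (POP_TARGET, slice(0, 2 * cfg.n_per_pop)),
        (POP_SRC1, slice(2 * cfg.n_per_pop, 4 * cfg.n_per_pop)),
        (POP_SRC2, slice(4 * cfg.n_per_pop, 6 * cfg.n_per_pop)),
    ):
        derived[pop] = hap[:, sl].mean(axis=1)
    ancestry = pd.Series(
        np.concatenate(
            [
                np.full(cfg.n_per_pop, cfg.admixture_fraction),
                np.ones(cfg.n_per_pop),
                np.zeros(cfg.n_per_pop),
            ]
        ),
        index=samples,
        name="source1_ancestry",
    )
    truth = SimTruth(
        site_class=labels,
        derived_freqs=derived,
        ancestry=ancestry,
        founder_freqs=founder,
        admixture_fraction=cfg.admixture_fraction,
        seed=cfg.seed,
    )
    variants = variant_table(
        chrom, pos, _BASES[ref_b], _BASES[alt_b], ancestral, labels
    )
    return panel, truth, variants


# ---------------------------------------------------------------------------
# Sequencing emulation
# ---------------------------------------------------------------------------

_PL_CAP = 255


def emit_sequencing_data(panel: HaplotypePanel, cfg: SimConfig) -> GenotypePanel:
    """Emulate short-read sequencing of the cohort.

    Per site and individual: read depth ~ Poisson(mean_depth); each read
    reports the true allele with probability 1 - error_rate, the other
    allele otherwise.  Genotype likelihoods follow the symmetric-error
    binomial model (alt-read probability e, 1/2, 1-e for the three
    genotypes), Phred-scaled, integer-rounded, capped at 255 and
    normalised so the best genotype has PL 0.  Zero-depth entries carry a
    flat likelihood triple and a missing genotype call.
    """
    if panel.n_sites == 0:
        raise ValueError("empty haplotype panel")
    if cfg.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    dose = panel.dosage()
    n_sites, n_ind = dose.shape
    depth = rng.poisson(cfg.mean_depth, size=(n_sites, n_ind))
    e = cfg.error_rate
    p_read_alt = np.array([e, 0.5, 1.0 - e])[dose]
    alt_reads = rng.binomial(depth, p_read_alt)

    pl = genotype_pl(alt_reads, depth, e)
    gp = pl_to_gp(pl)
    gt = np.where(depth > 0, np.argmin(pl, axis=2), MISSING).astype(np.int8)
    return GenotypePanel(
        chrom=panel.chrom,
        pos=panel.pos,
        ref=np.full(n_sites, "", dtype=object),
        alt=np.full(n_sites, "", dtype=object),
        gt=gt,
        gp=gp,
        samples=list(panel.samples),
        pops=panel.pops,
        dp=depth,
        pl=pl,
    )


def genotype_pl(alt_reads: np.ndarray, depth: np.ndarray, error_rate: float):
    """Phred-scaled, normalised genotype likelihoods from alt-read counts.

    Returns an integer array (..., 3); zero-depth entries get the flat
    triple (0, 0, 0), i.e. no information.
    """
    probs = np.array([error_rate, 0.5, 1.0 - error_rate])
    with np.errstate(divide="ignore"):
        ll = np.stack(
            [binom.logpmf(alt_reads, depth, p) for p in probs], axis=-1
        ) / np.log(10.0)
    ll = np.where(np.isfinite(ll), ll, -np.inf)
    best = ll.max(axis=-1, keepdims=True)
    pl = np.rint(-10.0 * (ll - best))
    pl = np.minimum(np.nan_to_num(pl, posinf=_PL_CAP), _PL_CAP).astype(np.int32)
    return pl


def pl_to_gp(pl: np.ndarray) -> np.ndarray:
    """De-Phred and renormalise PL triples into genotype probabilities."""
    gl = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
    return gl / gl.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Environmental (GEA) truth
# ---------------------------------------------------------------------------


@dataclass
class EnvTruth:
    b_true: np.ndarray
    affected: np.ndarray
    baseline: np.ndarray
    pop_freqs: np.ndarray  # (n_snp, n_pop)
    scores_std: np.ndarray


def generate_environment(
    n_pops: int,
    n_pcs: int,
    effect_scale: float,
    seed: int,
    n_snps: int = 2000,
    n_covariates: int = 19,
    affected_fraction: float = 0.1,
    noise_sd: float = 0.02,
):
    """Environmental covariates, PCA design, and GEA-structured population
    allele frequencies with retained truth.

    A latent (n_pops x n_pcs) environmental structure generates the
    covariate matrix; allele-frequency deviations from a neutral baseline
    follow ``scores_std @ B_true.T`` at the affected SNPs plus Gaussian
    noise everywhere.  ``effect_scale`` sets the SD of the non-zero
    entries of B_true; 0 gives a no-association null.
    """
    from .offset import env_pca  # local import to avoid a cycle

    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(n_pops, n_pcs))
    mixing = rng.normal(size=(n_pcs, n_covariates))
    cov = latent @ mixing + rng.normal(scale=0.05, size=(n_pops, n_covariates))
    cov_df = pd.DataFrame(
        cov,
        index=[f"POP_{i:02d}" for i in range(n_pops)],
        columns=[f"bio{k + 1}" for k in range(n_covariates)],
    )
    design = env_pca(cov_df, n_keep=n_pcs)
    scores_std = (design.scores - design.scores.mean(axis=0)) / design.scores.std(
        axis=0
    )

    affected = rng.random(n_snps) < affected_fraction
    b_true = np.zeros((n_snps, n_pcs))
    b_true[affected] = rng.normal(scale=effect_scale, size=(affected.sum(), n_pcs))
    baseline = rng.uniform(0.1, 0.9, size=n_snps)
    f = (
        baseline[:, None]
        + b_true @ scores_std.T
        + rng.normal(scale=noise_sd, size=(n_snps, n_pops))
    )
    pop_freqs = np.clip(f, 0.01, 0.99)
    truth = EnvTruth(
        b_true=b_true,
        affected=affected,
        baseline=baseline,
        pop_freqs=pop_freqs,
        scores_std=scores_std,
    )
    return design, truth, cov_df


# ---------------------------------------------------------------------------
# Synthetic gene intervals (for scan annotation)
# ---------------------------------------------------------------------------


def synthetic_genes(
    cfg: SimConfig, gene_length: int = 20_000, spacing: int = 100_000
) -> pd.DataFrame:
    """Regularly tiled synthetic gene intervals (0-based half-open)."""
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        start = spacing // 2
        i = 0
        while start + gene_length < cfg.chrom_length:
            rows.append(
                {
                    "chrom": str(c),
                    "start": start,
                    "end": start + gene_length,
                    "name": f"GENE{c}_{i}",
                }
            )
            start += spacing
            i += 1
    return pd.DataFrame(rows)
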