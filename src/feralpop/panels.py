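"""In-memory containers for genotype, haplotype and variant data.

Coordinates: site positions are stored 1-based as printed in VCF; interval
arithmetic (gene annotation) converts to 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: functional classes, ordered from least to most severe
VARIANT_CLASSES = ("intergenic", "synonymous", "ns_tolerated", "ns_deleterious", "lof")

MISSING = -1


@dataclass
class GenotypePanel:
    """Per-site, per-individual genotype calls and genotype likelihoods.

    Attributes
    ----------
    chrom, pos, ref, alt : arrays of length n_sites
        Site keys. ``pos`` is 1-based.
    gt : (n_sites, n_samples) int8
        Alt-allele dosage 0/1/2, ``-1`` for missing.
    gp : (n_sites, n_samples, 3) float
        Genotype probabilities: de-Phred-ed likelihoods ``10**(-PL/10)``
        renormalised to sum to one.  Missing entries hold the flat triple.
    samples : list of str
    pops : (n_samples,) array of population labels
    dp : optional (n_sites, n_samples) int read depths
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    gp: np.ndarray
    samples: list
    pops: np.ndarray
    dp: np.ndarray | None = None
    pl: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.gp = np.asarray(self.gp, dtype=float)
        self.pops = np.asarray(self.pops)
        if self.gt.shape != self.gp.shape[:2]:
            raise ValueError("gt and gp shapes disagree")
        if self.gp.shape[2] != 3:
            raise ValueError("gp must have three genotype columns")
        if len(self.samples) != self.gt.shape[1]:
            raise ValueError("sample list length does not match gt columns")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    @property
    def populations(self) -> list:
        seen = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(self.pops == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        return idx

    def missing_mask(self) -> np.ndarray:
        return self.gt == MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            gt=self.gt[index],
            gp=self.gp[index],
            samples=list(self.samples),
            pops=self.pops,
            dp=None if self.dp is None else self.dp[index],
            pl=None if self.pl is None else self.pl[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            gt=self.gt[:, index],
            gp=self.gp[:, index],
            samples=[self.samples[i] for i in index],
            pops=self.pops[index],
            dp=None if self.dp is None else self.dp[:, index],
            pl=None if self.pl is None else self.pl[:, index],
        )

    def for_population(self, pop: str) -> "GenotypePanel":
        return self.take_samples(self.sample_indices(pop))


@dataclass
class HaplotypePanel:
    """Phased haplotypes on a genetic map.

    ``hap`` has shape (n_sites, n_haplotypes); haplotypes 2i and 2i+1
    belong to diploid individual i.  ``cm`` is the genetic-map position.
    """

    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray
    hap: np.ndarray
    samples: list
    pops: np.ndarray  # one label per individual

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        self.hap = np.asarray(self.hap, dtype=np.int8)
        self.pops = np.asarray(self.pops)
        if self.hap.shape[1] != 2 * len(self.samples):
            raise ValueError("haplotype count must be twice the sample count")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if np.any(np.diff(self.cm[sel]) < 0):
                raise ValueError(f"map positions decrease on chromosome {c}")

    @property
    def n_sites(self) -> int:
        return self.hap.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def hap_pops(self) -> np.ndarray:
        return np.repeat(self.pops, 2)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_sites, n_samples)."""
        return (self.hap[:, 0::2] + self.hap[:, 1::2]).astype(np.int8)

    def for_population(self, pop: str) -> "HaplotypePanel":
        idx = np.flatnonzero(self.pops == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        hap_idx = np.sort(np.concatenate([2 * idx, 2 * idx + 1]))
        return HaplotypePanel(
            chrom=self.chrom,
            pos=self.pos,
            cm=self.cm,
            hap=self.hap[:, hap_idx],
            samples=[self.samples[i] for i in idx],
            pops=self.pops[idx],
        )

    def take_sites(self, index: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            cm=self.cm[index],
            hap=self.hap[index],
            samples=list(self.samples),
            pops=self.pops,
        )


def variant_table(chrom, pos, ref, alt, ancestral, vclass) -> pd.DataFrame:
    """Assemble the per-site annotation table.

    ``ancestral`` holds the ancestral allele base (or '.' when the site
    could not be polarised); ``vclass`` one of :data:`VARIANT_CLASSES`.
    """
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref),
            "alt": np.asarray(alt),
            "ancestral": np.asarray(ancestral),
            "vclass": np.asarray(vclass),
        }
    )
    bad = set(df["vclass"].unique()) - set(VARIANT_CLASSES) - {"."}
    if bad:
        raise ValueError(f"unknown variant classes: {sorted(bad)}")
    return df


def derived_is_alt(variants: pd.DataFrame) -> np.ndarray:
    """Boolean per site: derived allele is the alt allele.

    Only meaningful where the ancestral allele is assigned; sites with
    ancestral '.' return False and should be masked by ``polarized``.
    """
    return (variants["ancestral"] == variants["ref"]).to_numpy()


def polarized_mask(variants: pd.DataFrame) -> np.ndarray:
    anc = variants["ancestral"].to_numpy()
    return (anc == variants["ref"].to_numpy()) | (anc == variants["alt"].to_numpy())
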