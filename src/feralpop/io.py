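"""Readers and writers for the package's file formats.

VCF 4.2 (GT:PL:DP) is written as plain text and read back with cyvcf2.
All tabular side files (annotation, population map, environment, genetic
map, gene intervals, haplotypes) are TSV.  VCF positions are 1-based;
gene intervals are stored 0-based half-open.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panels import MISSING, GenotypePanel, HaplotypePanel
from .simdata import pl_to_gp

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path, variants: pd.DataFrame | None = None):
    """Write the genotype panel as a VCF 4.2 text file with GT:PL:DP.

    ``variants`` supplies REF/ALT bases when the panel's own ref/alt
    fields are empty (as for freshly emitted sequencing data).
    """
    ref = panel.ref
    alt = panel.alt
    if variants is not None:
        ref = variants["ref"].to_numpy()
        alt = variants["alt"].to_numpy()
    if panel.pl is None:
        with np.errstate(divide="ignore"):
            best = panel.gp.max(axis=2, keepdims=True)
            pl = np.rint(-10.0 * np.log10(panel.gp / best)).astype(int)
    else:
        pl = panel.pl
    dp = panel.dp if panel.dp is not None else np.zeros(panel.gt.shape, dtype=int)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
            '"Phred-scaled genotype likelihoods">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for i in range(panel.n_sites):
            cells = [
                f"{_GT_STRINGS[int(panel.gt[i, j])]}:"
                f"{pl[i, j, 0]},{pl[i, j, 1]},{pl[i, j, 2]}:{int(dp[i, j])}"
                for j in range(panel.n_samples)
            ]
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t.\t{ref[i]}\t{alt[i]}"
                f"\t.\t.\t.\tGT:PL:DP\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path, popmap: pd.DataFrame | pd.Series | dict) -> GenotypePanel:
    """Read a VCF with PL fields into a :class:`GenotypePanel`.

    ``popmap`` maps sample name -> population label (dict, Series, or a
    DataFrame with columns sample/pop).  PL triples are de-Phred-ed as
    10^(-PL/10) and renormalised into genotype probabilities.
    """
    if isinstance(popmap, pd.DataFrame):
        popmap = dict(zip(popmap["sample"], popmap["pop"]))
    elif isinstance(popmap, pd.Series):
        popmap = popmap.to_dict()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in popmap]
    if missing_pop:
        raise ValueError(f"population map lacks samples: {missing_pop}")
    chrom, pos, ref, alt = [], [], [], []
    gts, pls, dps = [], [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        code = np.asarray(v.gt_types)
        gts.append(np.select([code == 0, code == 1, code == 3], [0, 1, 2], -1))
        pl = v.format("PL")
        pls.append(
            pl.astype(np.int32)
            if pl is not None
            else np.zeros((len(samples), 3), dtype=np.int32)
        )
        dp = v.format("DP")
        dps.append(
            dp.reshape(-1).astype(int)
            if dp is not None
            else np.zeros(len(samples), dtype=int)
        )
    pl_arr = np.stack(pls)
    return GenotypePanel(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        gt=np.stack(gts).astype(np.int8),
        gp=pl_to_gp(pl_arr),
        samples=samples,
        pops=np.asarray([popmap[s] for s in samples]),
        dp=np.stack(dps),
        pl=pl_arr,
    )


# ---------------------------------------------------------------------------
# TSV side tables
# ---------------------------------------------------------------------------


def write_annotation(variants: pd.DataFrame, path):
    variants.rename(
        columns={
            "chrom": "CHROM", "pos": "POS", "ref": "REF", "alt": "ALT",
            "ancestral": "AA", "vclass": "CLASS",
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    return df.rename(
        columns={
            "CHROM": "chrom", "POS": "pos", "REF": "ref", "ALT": "alt",
            "AA": "ancestral", "CLASS": "vclass",
        }
    )


def write_popmap(samples, pops, path):
    pd.DataFrame({"sample": samples, "pop": pops}).to_csv(
        path, sep="\t", index=False
    )


def read_popmap(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_environment(cov_df: pd.DataFrame, path):
    cov_df.rename_axis("pop").to_csv(path, sep="\t")


def read_environment(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="pop")


def write_genetic_map(chrom, pos, cm, path):
    pd.DataFrame({"CHROM": chrom, "POS": pos, "CM": cm}).to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"CHROM": str})


def write_genes(genes: pd.DataFrame, path):
    genes.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_haplotypes(panel: HaplotypePanel, path):
    """Haplotype TSV: one row per site (chrom, pos, cm, then one column
    per haplotype named sample_0 / sample_1)."""
    cols = {"chrom": panel.chrom, "pos": panel.pos, "cm": panel.cm}
    for j, s in enumerate(panel.samples):
        cols[f"{s}_0"] = panel.hap[:, 2 * j]
        cols[f"{s}_1"] = panel.hap[:, 2 * j + 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_haplotypes(path, popmap: pd.DataFrame | dict) -> HaplotypePanel:
    if isinstance(popmap, pd.DataFrame):
        popmap = dict(zip(popmap["sample"], popmap["pop"]))
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hap_cols = [c for c in df.columns if c.endswith(("_0", "_1"))]
    samples = list(dict.fromkeys(c[:-2] for c in hap_cols))
    hap = np.column_stack(
        [df[f"{s}_{k}"].to_numpy() for s in samples for k in (0, 1)]
    ).astype(np.int8)
    return HaplotypePanel(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(),
        cm=df["cm"].to_numpy(),
        hap=hap,
        samples=samples,
        pops=np.asarray([popmap[s] for s in samples]),
    )


def write_fixtures(
    out_dir,
    genotypes: GenotypePanel,
    variants: pd.DataFrame,
    haplotypes: HaplotypePanel | None = None,
    env_covariates: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
) -> dict:
    """Write the standard fixture set; returns the path of each file.

    Files: cohort.vcf (GT:PL:DP), annotation.tsv, populations.tsv,
    genetic_map.tsv, and optionally haplotypes.tsv, environment.tsv,
    genes.tsv.  Everything round-trips losslessly through the matching
    readers in this module.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    write_vcf(genotypes, p("cohort.vcf"), variants=variants)
    write_annotation(variants, p("annotation.tsv"))
    write_popmap(genotypes.samples, genotypes.pops, p("populations.tsv"))
    if haplotypes is not None:
        write_haplotypes(haplotypes, p("haplotypes.tsv"))
        write_genetic_map(
            haplotypes.chrom, haplotypes.pos, haplotypes.cm, p("genetic_map.tsv")
        )
    if env_covariates is not None:
        write_environment(env_covariates, p("environment.tsv"))
    if genes is not None:
        write_genes(genes, p("genes.tsv"))
    return paths
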