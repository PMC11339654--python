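"""Simulate → estimate → report pipeline.

Orchestrates the package's stages on a synthetic cohort (or pre-existing
fixture files), writing one TSV per stage plus a human-readable summary.
Every output directory carries ``run_metadata.yaml`` with the seed and a
hash of the configuration, and the log records per-stage site counts and
exclusions.  Reruns with an identical configuration produce byte-identical
numeric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import chronology, glfreq, io, load, offset, popstruct, scan, simdata
from .panels import VARIANT_CLASSES, polarized_mask
from .simdata import POP_SRC1, POP_SRC2, POP_TARGET, SimConfig

log = logging.getLogger("feralpop")

ALL_STAGES = ("simulate", "freqs", "load", "fstats", "kinship", "offset",
              "scan", "chrono")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative pipeline configuration with the analysis defaults
    pre-filled: 250-SNP jackknife blocks for f-statistics, 100 blocks for
    RX/Y, scan with xi = 2 and MAF > 0.01, 7 environmental PCs, and the
    0.001/0.999 segregating-site thresholds."""

    out_dir: str = "feralpop_run"
    seed: int = 1
    stages: tuple = ALL_STAGES
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    fstat_block_snps: int = 250
    rxy_blocks: int = 100
    scan_xi: float = 2.0
    scan_maf: float = 0.01
    scan_threshold_mode: str = "mc"
    scan_n_perm: int = 1000
    env_n_pcs: int = 7
    env_n_pops: int = 32
    env_effect_scale: float = 0.3
    # input files for running from fixtures instead of simulating
    vcf: str | None = None
    annotation: str | None = None
    popmap: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        return cls(sim=sim, stages=stages, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_inputs(paths: dict) -> list[str]:
    """Schema and consistency diagnostics for a fixture set.

    ``paths`` maps names (vcf, annotation, popmap, ...) to files.  Fatal
    problems raise ValueError; non-fatal findings are returned as warning
    strings.
    """
    warnings_out = []
    for name, p in paths.items():
        if p is not None and not os.path.exists(p):
            raise ValueError(f"{name} file does not exist: {p}")
    popmap = io.read_popmap(paths["popmap"]) if paths.get("popmap") else None
    if paths.get("vcf"):
        from cyvcf2 import VCF

        vcf = VCF(str(paths["vcf"]))
        samples = set(vcf.samples)
        last = {}
        for n, v in enumerate(vcf):
            if v.CHROM in last and v.POS < last[v.CHROM]:
                raise ValueError(
                    f"VCF positions unsorted at {v.CHROM}:{v.POS} (record {n + 1})"
                )
            last[v.CHROM] = v.POS
            if len(v.ALT) != 1:
                warnings_out.append(
                    f"non-biallelic record at {v.CHROM}:{v.POS}"
                )
        if popmap is not None:
            absent = sorted(set(popmap["sample"]) - samples)
            if absent:
                warnings_out.append(
                    f"population table names absent samples: {absent}"
                )
    if paths.get("annotation"):
        ann = io.read_annotation(paths["annotation"])
        need = {"chrom", "pos", "ref", "alt", "ancestral", "vclass"}
        if not need <= set(ann.columns):
            raise ValueError(
                f"annotation table misses columns {need - set(ann.columns)}"
            )
        bad = set(ann["vclass"]) - set(VARIANT_CLASSES) - {"."}
        if bad:
            warnings_out.append(f"unknown variant classes in annotation: {bad}")
    return warnings_out


def _counter(stage: str, **counts):
    log.info("[%s] %s", stage, ", ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns a dict of
    output tables.  Partial outputs are preserved on stage failure."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    with open(os.path.join(cfg.out_dir, "run_metadata.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    results: dict = {}
    summary = [f"feralpop run (seed={cfg.seed}, config={meta['config_hash']})"]

    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    needs_genotypes = bool(
        set(cfg.stages) & {"simulate", "freqs", "load", "fstats", "kinship",
                           "scan"}
    )
    gpanel = variants = hap_panel = truth = genes = None
    stage = "simulate"
    try:
        if not needs_genotypes:
            pass
        elif "simulate" in cfg.stages:
            hap_panel, truth, variants = simdata.simulate_cohort(sim)
            gpanel = simdata.emit_sequencing_data(hap_panel, sim)
            genes = simdata.synthetic_genes(sim)
            io.write_fixtures(
                os.path.join(cfg.out_dir, "fixtures"),
                gpanel,
                variants,
                haplotypes=hap_panel,
                genes=genes,
            )
            _counter(stage, sites=gpanel.n_sites, samples=gpanel.n_samples)
        else:
            popmap = io.read_popmap(cfg.popmap)
            gpanel = io.read_vcf(cfg.vcf, popmap)
            variants = io.read_annotation(cfg.annotation)
            _counter(stage, sites=gpanel.n_sites, samples=gpanel.n_samples)
        results["genotypes"] = gpanel
        results["variants"] = variants

        if set(cfg.stages) & {"freqs", "load"}:
            pol = polarized_mask(variants)
            freq_table = glfreq.population_frequency_table(gpanel, variants)
        if "freqs" in cfg.stages:
            stage = "freqs"
            rows = []
            for pop in gpanel.populations:
                af = freq_table[f"af_{pop}"].to_numpy()
                daf = freq_table[f"daf_{pop}"].to_numpy()
                counts = glfreq.count_segregating_fixed(af, daf, pol)
                sub = gpanel.for_population(pop)
                n_dip = (~(sub.gt == -1)).sum(axis=1)
                counts["het"] = glfreq.expected_heterozygosity(af, n_dip)
                counts["pop"] = pop
                rows.append(counts)
            freq_summary = pd.DataFrame(rows).set_index("pop")
            freq_table.to_csv(
                os.path.join(cfg.out_dir, "frequencies.tsv"), sep="\t",
                index=False,
            )
            freq_summary.to_csv(
                os.path.join(cfg.out_dir, "diversity.tsv"), sep="\t"
            )
            results["diversity"] = freq_summary
            _counter(stage, sites=len(freq_table))
            summary.append(
                "Diversity: "
                + "; ".join(
                    f"{p}: {freq_summary.loc[p, 'segregating']} segregating, "
                    f"het={freq_summary.loc[p, 'het']:.4f}"
                    for p in freq_summary.index
                )
            )

        if "load" in cfg.stages:
            stage = "load"
            ns_s = load.ns_s_het_ratio(gpanel, variants)
            parts = [ns_s.rename("ns_s_het_ratio").to_frame()]
            for cls in ("ns_deleterious", "lof"):
                if (variants["vclass"] == cls).any():
                    mr = load.masked_realized_load(gpanel, variants, cls)
                    parts.append(
                        mr[["masked", "realized"]].add_prefix(f"{cls}_")
                    )
            load_table = pd.concat(parts, axis=1)
            load_table.rename_axis("sample").to_csv(
                os.path.join(cfg.out_dir, "load_individual.tsv"), sep="\t"
            )
            results["load_individual"] = load_table

            rxy_rows = []
            fx = freq_table[f"daf_{POP_TARGET}"].to_numpy()
            fy = freq_table[f"daf_{POP_SRC1}"].to_numpy()
            cls_masks = {
                c: (variants["vclass"] == c).to_numpy() & pol
                for c in VARIANT_CLASSES
            }
            for cls in ("ns_tolerated", "ns_deleterious", "lof"):
                try:
                    r = load.rxy(
                        fx, fy, cls_masks[cls], cls_masks["intergenic"],
                        n_blocks=cfg.rxy_blocks,
                    )
                except (ValueError, ZeroDivisionError) as err:
                    log.warning("[load] RX/Y skipped for %s: %s", cls, err)
                    continue
                rxy_rows.append(
                    {
                        "class": cls,
                        "rxy_standardized": r.standardized,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "n_sites": r.n_class_sites,
                    }
                )
            if rxy_rows:
                rxy_table = pd.DataFrame(rxy_rows)
                rxy_table.to_csv(
                    os.path.join(cfg.out_dir, "rxy.tsv"), sep="\t", index=False
                )
                results["rxy"] = rxy_table
            _counter(stage, individuals=len(load_table), rxy_classes=len(rxy_rows))
            summary.append(
                f"Mean NS/S het ratio: {np.nanmean(ns_s.to_numpy()):.3f}"
            )

        if "fstats" in cfg.stages:
            stage = "fstats"
            blocks = popstruct.BlockScheme.contiguous(
                gpanel.n_sites, cfg.fstat_block_snps
            )
            wc = popstruct.wc_f_statistics(gpanel, blocks=blocks)
            pops = gpanel.populations
            f3cfg = [("f3", pops[0], pops[1], pops[2])]
            fstats = popstruct.f_statistics(gpanel, f3cfg, blocks=blocks)
            rows = [
                {"name": r.name, "estimate": r.estimate, "se": r.se, "z": r.z}
                for r in list(wc.values()) + fstats
            ]
            ftable = pd.DataFrame(rows)
            ftable.to_csv(
                os.path.join(cfg.out_dir, "fstats.tsv"), sep="\t", index=False
            )
            results["fstats"] = ftable
            _counter(stage, statistics=len(ftable), blocks=blocks.n_blocks)
            summary.append(
                f"Global FST = {wc['FST'].estimate:.4f} "
                f"(SE {wc['FST'].se:.4f})"
            )

        if "kinship" in cfg.stages:
            stage = "kinship"
            target = gpanel.for_population(POP_TARGET)
            kin = popstruct.kinship_matrix(target)
            pairs = []
            for i in range(len(kin)):
                for j in range(i + 1, len(kin)):
                    phi = kin.iloc[i, j]
                    pairs.append(
                        {
                            "a": kin.index[i],
                            "b": kin.index[j],
                            "phi": phi,
                            "degree": popstruct.classify_degree(phi),
                        }
                    )
            kin_table = pd.DataFrame(pairs)
            kin_table.to_csv(
                os.path.join(cfg.out_dir, "kinship.tsv"), sep="\t", index=False
            )
            results["kinship"] = kin_table
            _counter(stage, pairs=len(kin_table))

        if "offset" in cfg.stages:
            stage = "offset"
            design, env_truth, cov = simdata.generate_environment(
                cfg.env_n_pops, cfg.env_n_pcs, cfg.env_effect_scale,
                seed=cfg.seed + 7,
            )
            b_hat = offset.estimate_gea_coefficients(
                env_truth.pop_freqs, design.scores
            )
            go = offset.offset_table(design, b_hat, design.pop_names[0])
            go.to_csv(
                os.path.join(cfg.out_dir, "genetic_offset.tsv"), sep="\t",
                index=False,
            )
            results["genetic_offset"] = go
            _counter(stage, populations=len(go), snps=len(b_hat))
            summary.append(
                f"Genetic offset: max GO {go['go'].max():.4f} at "
                f"{go.loc[go['go'].idxmax(), 'pop']}"
            )

        if "scan" in cfg.stages and hap_panel is not None:
            stage = "scan"
            tpanel = hap_panel.for_population(POP_TARGET)
            ihs_df = scan.ihs(tpanel, maf_min=cfg.scan_maf)
            ihs_df["pihs"] = scan.p_transform(ihs_df["ihs"].to_numpy(), "ihs")
            windows = scan.genome_local_score(
                ihs_df.dropna(subset=["pihs"]),
                "pihs",
                xi=cfg.scan_xi,
                threshold_mode=cfg.scan_threshold_mode,
                n_perm=cfg.scan_n_perm,
                seed=cfg.seed,
            )
            if genes is not None and len(windows):
                windows = scan.annotate_regions(windows, genes)
            ihs_df.to_csv(
                os.path.join(cfg.out_dir, "scan_ihs.tsv"), sep="\t", index=False
            )
            windows.to_csv(
                os.path.join(cfg.out_dir, "scan_windows.tsv"), sep="\t",
                index=False,
            )
            results["scan_windows"] = windows
            _counter(
                stage,
                snps=int(np.isfinite(ihs_df["ihs"]).sum()),
                windows=len(windows),
            )
            summary.append(f"Selection scan: {len(windows)} candidate windows")

        if "chrono" in cfg.stages:
            stage = "chrono"
            scale = chronology.TimeScale()
            rates = chronology.hbd_rate_grid()
            chrono = pd.DataFrame(
                {
                    "rc": rates,
                    "segment_morgans": [
                        chronology.hbd_class_properties(r)[0] for r in rates
                    ],
                    "ancestor_generations": [
                        chronology.hbd_class_properties(r)[1] for r in rates
                    ],
                }
            )
            chrono.to_csv(
                os.path.join(cfg.out_dir, "hbd_classes.tsv"), sep="\t",
                index=False,
            )
            results["hbd_classes"] = chrono
            year = chronology.generations_to_year(cfg.sim.t_bottleneck, scale)
            summary.append(
                f"Founding {cfg.sim.t_bottleneck} generations before "
                f"{scale.reference_year} ≈ calendar year {year}"
            )
    except Exception:
        log.error("stage %r failed; partial outputs kept in %s", stage,
                  cfg.out_dir)
        raise

    with open(os.path.join(cfg.out_dir, "summary.txt"), "w") as fh:
        fh.write("\n".join(summary) + "\n")
    results["summary"] = summary
    return results
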