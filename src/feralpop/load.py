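"""Genetic-load statistics by functional class.

Implements the per-individual NS/S heterozygote ratio, the masked load
(proportion of heterozygous genotypes, deleterious alleles hidden from
selection) and realized load (proportion of genotypes homozygous for the
derived allele), the RX/Y relative derived-allele statistic between two
populations with a 100-block jackknife CI, and additive genomic prediction
of breeding values from an external SNP-effect table.

Heterozygote and homozygote counts default to expectations over genotype
probabilities; ``hard_calls=True`` switches to the called genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel, derived_is_alt, polarized_mask
from .popstruct import BlockScheme, block_jackknife_ratio


def _class_mask(variants: pd.DataFrame, vclass: str) -> np.ndarray:
    m = (variants["vclass"] == vclass).to_numpy()
    if not m.any():
        raise ValueError(f"no sites in class {vclass!r}")
    return m


def _het_expectation(panel: GenotypePanel, mask: np.ndarray, hard_calls: bool):
    """Per-individual expected het count and called-site count over the
    masked sites."""
    called = panel.gt[mask] != MISSING
    if hard_calls:
        het = np.where(called, panel.gt[mask] == 1, 0.0)
    else:
        het = np.where(called, panel.gp[mask][:, :, 1], 0.0)
    return het.sum(axis=0), called.sum(axis=0)


def ns_s_het_ratio(
    panel: GenotypePanel, variants: pd.DataFrame, hard_calls: bool = False
) -> pd.Series:
    """Per-individual ratio of nonsynonymous to synonymous heterozygous
    genotypes (NS = tolerated + deleterious missense).

    Individuals with zero synonymous heterozygotes get NaN.
    """
    ns_mask = (
        variants["vclass"].isin(["ns_tolerated", "ns_deleterious"]).to_numpy()
    )
    if not ns_mask.any():
        raise ValueError("no nonsynonymous sites present")
    s_mask = _class_mask(variants, "synonymous")
    ns_het, _ = _het_expectation(panel, ns_mask, hard_calls)
    s_het, _ = _het_expectation(panel, s_mask, hard_calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(s_het > 0, ns_het / np.maximum(s_het, 1e-300), np.nan)
    return pd.Series(ratio, index=panel.samples, name="ns_s_het_ratio")


def masked_realized_load(
    panel: GenotypePanel,
    variants: pd.DataFrame,
    vclass: str,
    hard_calls: bool = False,
) -> pd.DataFrame:
    """Masked and realized load per individual for one functional class.

    masked  = proportion of the individual's called class sites that are
              heterozygous;
    realized = proportion homozygous for the derived allele.
    Only polarised sites of the class are used; an individual with no
    called class site gets NaN for both.  Per individual,
    masked + realized + P(hom-ancestral) = 1.
    """
    mask = _class_mask(variants, vclass) & polarized_mask(variants)
    if not mask.any():
        raise ValueError(f"no polarised sites in class {vclass!r}")
    alt_der = derived_is_alt(variants)[mask]
    gt = panel.gt[mask]
    gp = panel.gp[mask]
    # orient genotype probabilities as (hom-ancestral, het, hom-derived)
    gp = np.where(alt_der[:, None, None], gp, gp[:, :, ::-1])
    called = gt != MISSING
    n_called = called.sum(axis=0).astype(float)
    if hard_calls:
        der_dose = np.where(alt_der[:, None], gt, 2 - gt)
        het = np.where(called, der_dose == 1, 0.0).sum(axis=0)
        homd = np.where(called, der_dose == 2, 0.0).sum(axis=0)
    else:
        het = np.where(called, gp[:, :, 1], 0.0).sum(axis=0)
        homd = np.where(called, gp[:, :, 2], 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        masked = np.where(n_called > 0, het / n_called, np.nan)
        realized = np.where(n_called > 0, homd / n_called, np.nan)
    return pd.DataFrame(
        {"masked": masked, "realized": realized, "n_sites": n_called.astype(int)},
        index=panel.samples,
    )


@dataclass
class RxyResult:
    raw: float
    raw_normalizer: float
    standardized: float
    se: float
    ci_low: float
    ci_high: float
    n_class_sites: int
    n_normalizer_sites: int


def rxy_raw(fx: np.ndarray, fy: np.ndarray) -> float:
    """Raw RX/Y = sum fX(1-fY) / sum fY(1-fX) over sites.

    fX, fY are derived-allele frequencies in populations X and Y; the
    numerator is the summed probability of sampling a derived allele in X
    and not in Y.
    """
    num = float(np.nansum(fx * (1 - fy)))
    den = float(np.nansum(fy * (1 - fx)))
    if den == 0:
        raise ZeroDivisionError("RX/Y denominator sums to zero")
    return num / den


def rxy(
    fx: np.ndarray,
    fy: np.ndarray,
    class_mask: np.ndarray,
    normalizer_mask: np.ndarray,
    n_blocks: int = 100,
) -> RxyResult:
    """Standardized RX/Y with a leave-one-block-out jackknife 95% CI.

    The class statistic is divided by the same statistic on the
    normalizer (intergenic) sites, correcting for branch-length
    differences.  The jackknife removes, in turn, each of ``n_blocks``
    consecutive-SNP blocks of equal SNP count (built separately on the
    class and normalizer site lists, dropped jointly by block index), and
    the CI is estimate +/- 1.96 SE.
    """
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    cm = np.asarray(class_mask, dtype=bool) & np.isfinite(fx) & np.isfinite(fy)
    nm = np.asarray(normalizer_mask, dtype=bool) & np.isfinite(fx) & np.isfinite(fy)
    if cm.sum() < n_blocks or nm.sum() < n_blocks:
        raise ValueError("fewer class or normalizer sites than jackknife blocks")

    def sums(mask):
        return fx[mask] * (1 - fy[mask]), fy[mask] * (1 - fx[mask])

    cnum, cden = sums(cm)
    nnum, nden = sums(nm)
    raw = cnum.sum() / cden.sum()
    raw_norm = nnum.sum() / nden.sum()
    est = raw / raw_norm

    cb = BlockScheme.equal_count(cm.sum(), n_blocks).block_id
    nb = BlockScheme.equal_count(nm.sum(), n_blocks).block_id
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        ck, nk = cb != b, nb != b
        loo[b] = (cnum[ck].sum() / cden[ck].sum()) / (
            nnum[nk].sum() / nden[nk].sum()
        )
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    return RxyResult(
        raw=float(raw),
        raw_normalizer=float(raw_norm),
        standardized=float(est),
        se=se,
        ci_low=float(est - 1.96 * se),
        ci_high=float(est + 1.96 * se),
        n_class_sites=int(cm.sum()),
        n_normalizer_sites=int(nm.sum()),
    )


def predict_height(
    panel: GenotypePanel, effects: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Additive breeding values: per individual, the sum over matched SNPs
    of allele dosage times the reported allele effect.

    ``effects`` columns: chrom, pos, allele, effect.  The effect allele
    must match the panel's ref or alt at the site; unmatched or absent
    variants are dropped and counted.  Returns (per-individual values,
    per-population summary, n_dropped).
    """
    key = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "ref": panel.ref,
            "alt": panel.alt,
            "row": np.arange(panel.n_sites),
        }
    )
    merged = effects.merge(key, on=["chrom", "pos"], how="inner")
    use_alt = merged["allele"] == merged["alt"]
    use_ref = merged["allele"] == merged["ref"]
    matched = merged[use_alt | use_ref]
    n_dropped = len(effects) - len(matched)
    rows = matched["row"].to_numpy()
    sign_alt = (matched["allele"] == matched["alt"]).to_numpy()
    gt = panel.gt[rows].astype(float)
    gt[panel.gt[rows] == MISSING] = np.nan
    dosage = np.where(sign_alt[:, None], gt, 2.0 - gt)
    beta = matched["effect"].to_numpy()[:, None]
    values = np.nansum(dosage * beta, axis=0)
    series = pd.Series(values, index=panel.samples, name="breeding_value")
    summary = (
        pd.DataFrame({"value": values, "pop": panel.pops})
        .groupby("pop")["value"]
        .agg(["mean", "min", "max"])
    )
    return series, summary, int(n_dropped)
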