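"""Population structure statistics.

Weir & Cockerham (1984) analysis-of-variance F-statistics, Patterson-style
unbiased f2/f3/f4 statistics with the F4-ratio admixture-proportion
estimator, allele-sharing distances, and KING-robust kinship with
powers-of-two relationship-degree classification.  Standard errors come
from a block jackknife over contiguous SNP blocks (default 250 SNPs per
block), which is robust to linkage disequilibrium between nearby sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel

DEFAULT_BLOCK_SNPS = 250

#: relationship-degree bounds: 2^{-(2d+3)/2} for degree d; intervals are
#: closed on the lower end
_DEGREE_BOUNDS = {
    "duplicate": 2 ** -1.5,
    "first": 2 ** -2.5,
    "second": 2 ** -3.5,
    "third": 2 ** -4.5,
}


@dataclass
class BlockScheme:
    """Contiguous equal-SNP jackknife blocks in genome order.

    ``block_id`` maps each SNP to its block.  All blocks hold
    ``snps_per_block`` SNPs except possibly the last, which keeps the
    remainder.
    """

    block_id: np.ndarray
    snps_per_block: int

    @property
    def n_blocks(self) -> int:
        return int(self.block_id.max()) + 1 if self.block_id.size else 0

    @classmethod
    def contiguous(cls, n_snps: int, snps_per_block: int = DEFAULT_BLOCK_SNPS):
        """Blocks of ``snps_per_block`` consecutive SNPs; a final short
        block (< half size would be merged into nothing — it is kept)."""
        if n_snps < 1:
            raise ValueError("need at least one SNP")
        bid = np.arange(n_snps) // snps_per_block
        return cls(block_id=bid, snps_per_block=snps_per_block)

    @classmethod
    def equal_count(cls, n_snps: int, n_blocks: int):
        """Exactly ``n_blocks`` blocks with equal SNP counts; remainder
        SNPs are assigned to the last block."""
        if n_blocks < 2 or n_snps < n_blocks:
            raise ValueError("need n_snps >= n_blocks >= 2")
        size = n_snps // n_blocks
        bid = np.minimum(np.arange(n_snps) // size, n_blocks - 1)
        return cls(block_id=bid, snps_per_block=size)


@dataclass
class FStatResult:
    name: str
    estimate: float
    se: float
    z: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = self.estimate / self.se if self.se > 0 else np.nan
        self.ci_low = self.estimate - 1.96 * self.se
        self.ci_high = self.estimate + 1.96 * self.se


def block_jackknife_ratio(num: np.ndarray, den: np.ndarray, block_id: np.ndarray):
    """Delete-one-block jackknife for a ratio-of-sums estimator.

    ``num``/``den`` are per-SNP numerator and denominator contributions.
    Returns (estimate, SE).  With B blocks the SE is
    sqrt((B-1)/B * sum (theta_(i) - mean)^2).
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    tot_n, tot_d = np.nansum(num), np.nansum(den)
    if tot_d == 0:
        return np.nan, np.nan
    est = tot_n / tot_d
    nb = int(block_id.max()) + 1
    bn = np.bincount(block_id, weights=np.nan_to_num(num), minlength=nb)
    bd = np.bincount(block_id, weights=np.nan_to_num(den), minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_n - bn) / (tot_d - bd)
    loo = loo[np.isfinite(loo)]
    b = loo.size
    if b < 2:
        return est, np.nan
    se = float(np.sqrt((b - 1) / b * np.sum((loo - loo.mean()) ** 2)))
    return est, se


# ---------------------------------------------------------------------------
# Weir–Cockerham F-statistics
# ---------------------------------------------------------------------------


def _wc_components(counts_per_pop):
    """Per-site W&C (1984) variance components a, b, c.

    ``counts_per_pop``: list of (n_i, p_i, h_i) arrays per population with
    n_i diploid sample size, p_i alt frequency, h_i observed het
    proportion; each array has one entry per site.
    """
    r = len(counts_per_pop)
    n = np.stack([c[0] for c in counts_per_pop]).astype(float)  # (r, sites)
    p = np.stack([c[1] for c in counts_per_pop])
    h = np.stack([c[2] for c in counts_per_pop])
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    return a, b, c


def _pop_site_summaries(panel: GenotypePanel, pops):
    out = []
    for pop in pops:
        gt = panel.for_population(pop).gt
        called = gt != MISSING
        n = called.sum(axis=1)
        if gt.shape[1] < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 diploids")
        dose = np.where(called, gt, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = dose / (2.0 * n)
            h = np.where(called, gt == 1, False).sum(axis=1) / n
        out.append((n, p, h))
    return out


def wc_f_statistics(
    panel: GenotypePanel,
    pops: list | None = None,
    blocks: BlockScheme | None = None,
) -> dict:
    """Global FIT/FST/FIS, pairwise FST and per-population FIS.

    Hard genotype calls; SNPs monomorphic across all included populations
    are excluded.  Global statistics are ratios of variance-component sums
    over SNPs; jackknife SEs use the block scheme.
    """
    pops = list(pops) if pops is not None else panel.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if blocks is None:
        blocks = BlockScheme.contiguous(panel.n_sites)
    summaries = _pop_site_summaries(panel, pops)

    # polymorphic across the analysis set
    pooled_p = np.nansum(
        [2 * n * p for n, p, _ in summaries], axis=0
    ) / np.maximum(np.nansum([2 * n for n, _, _ in summaries], axis=0), 1)
    poly = (pooled_p > 0) & (pooled_p < 1)
    ok = poly & np.all([n > 0 for n, _, _ in summaries], axis=0)

    a, b, c = _wc_components([(n[ok], p[ok], h[ok]) for n, p, h in summaries])
    bid = blocks.block_id[ok]
    results = {}
    fst, fst_se = block_jackknife_ratio(a, a + b + c, bid)
    fit, fit_se = block_jackknife_ratio(a + b, a + b + c, bid)
    fis, fis_se = block_jackknife_ratio(b, b + c, bid)
    results["FST"] = FStatResult("FST", fst, fst_se)
    results["FIT"] = FStatResult("FIT", fit, fit_se)
    results["FIS"] = FStatResult("FIS", fis, fis_se)

    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            (ni, pi, hi), (nj, pj, hj) = summaries[i], summaries[j]
            pair_p = (2 * ni * pi + 2 * nj * pj) / np.maximum(2 * ni + 2 * nj, 1)
            sel = (pair_p > 0) & (pair_p < 1) & (ni > 0) & (nj > 0)
            aa, bb, cc = _wc_components(
                [(ni[sel], pi[sel], hi[sel]), (nj[sel], pj[sel], hj[sel])]
            )
            est, se = block_jackknife_ratio(aa, aa + bb + cc, blocks.block_id[sel])
            results[f"FST:{pops[i]}:{pops[j]}"] = FStatResult(
                f"FST:{pops[i]}:{pops[j]}", est, se
            )

    for pop, (n, p, h) in zip(pops, summaries):
        sel = (p > 0) & (p < 1) & (n > 1)
        est, se = block_jackknife_ratio(
            *_single_pop_fis_components(n[sel], p[sel], h[sel]),
            blocks.block_id[sel],
        )
        results[f"FIS:{pop}"] = FStatResult(f"FIS:{pop}", est, se)
    return results


def _single_pop_fis_components(n, p, h):
    """Within-population FIS variance components (Weir 1996-style):
    FIS = 1 - c/(b+c) with the r=1 reduction of the W&C components."""
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (n / (n - 1)) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
    c = h / 2.0
    return b, b + c


# ---------------------------------------------------------------------------
# Patterson f-statistics
# ---------------------------------------------------------------------------


def _freq_and_h(panel: GenotypePanel, pop: str):
    """Sample alt frequency and the unbiased heterozygosity correction
    term h = p(1-p) * n_hap/(n_hap - 1) from hard calls."""
    gt = panel.for_population(pop).gt
    called = gt != MISSING
    n_hap = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, gt, 0).sum(axis=1) / n_hap
        h = p * (1 - p) * n_hap / (n_hap - 1)
    return p, h, n_hap


def f2_contributions(panel, a, b):
    pa, ha, na = _freq_and_h(panel, a)
    pb, hb, nb = _freq_and_h(panel, b)
    return (pa - pb) ** 2 - ha / na - hb / nb


def f3_contributions(panel, target, b, c):
    pt, ht, nt = _freq_and_h(panel, target)
    pb, _, _ = _freq_and_h(panel, b)
    pc, _, _ = _freq_and_h(panel, c)
    return (pt - pb) * (pt - pc) - ht / nt


def f4_contributions(panel, a, b, c, d):
    pa, _, _ = _freq_and_h(panel, a)
    pb, _, _ = _freq_and_h(panel, b)
    pc, _, _ = _freq_and_h(panel, c)
    pd_, _, _ = _freq_and_h(panel, d)
    return (pa - pb) * (pc - pd_)


def f_statistics(
    panel: GenotypePanel,
    configurations: list,
    blocks: BlockScheme | None = None,
    z_threshold: float = -1.65,
) -> list:
    """Unbiased f2/f3/f4 estimates with block-jackknife SE and Z-scores.

    ``configurations`` is a list of tuples: ("f2", A, B), ("f3", A, B, C)
    for target A, or ("f4", A, B, C, D).  For f3, ``extra['admixed']``
    records the one-sided admixture call Z < -1.65.
    """
    if blocks is None:
        blocks = BlockScheme.contiguous(panel.n_sites)
    out = []
    for cfg in configurations:
        kind, *popargs = cfg
        if len(set(popargs)) != len(popargs):
            raise ValueError(f"overlapping population labels in {cfg}")
        if kind == "f2":
            contrib = f2_contributions(panel, *popargs)
        elif kind == "f3":
            contrib = f3_contributions(panel, *popargs)
        elif kind == "f4":
            contrib = f4_contributions(panel, *popargs)
        else:
            raise ValueError(f"unknown statistic {kind!r}")
        ok = np.isfinite(contrib)
        est, se = block_jackknife_ratio(
            contrib[ok], np.ones(ok.sum()), blocks.block_id[ok]
        )
        name = f"{kind}({popargs[0]};{','.join(popargs[1:])})" if kind == "f3" else (
            f"{kind}({popargs[0]},{popargs[1]};{popargs[2]},{popargs[3]})"
            if kind == "f4"
            else f"f2({popargs[0]},{popargs[1]})"
        )
        res = FStatResult(name, est, se)
        if kind == "f3":
            res.extra["admixed"] = bool(np.isfinite(res.z) and res.z < z_threshold)
        out.append(res)
    return out


def f4_ratio(
    panel: GenotypePanel,
    numerator: tuple,
    denominator: tuple,
    blocks: BlockScheme | None = None,
) -> FStatResult:
    """Admixture proportion alpha = f4(numerator)/f4(denominator) with a
    block-jackknife 95% CI.

    Both arguments are (A, B, C, D) quadruplets sharing the outgroup /
    reference topology required by the F4-ratio construction.
    """
    if blocks is None:
        blocks = BlockScheme.contiguous(panel.n_sites)
    num = f4_contributions(panel, *numerator)
    den = f4_contributions(panel, *denominator)
    ok = np.isfinite(num) & np.isfinite(den)
    est, se = block_jackknife_ratio(num[ok], den[ok], blocks.block_id[ok])
    if not np.isfinite(est):
        raise ZeroDivisionError("denominator f4 sums to zero; ratio undefined")
    res = FStatResult("F4-ratio", est, se)
    res.extra["numerator"] = numerator
    res.extra["denominator"] = denominator
    return res


# ---------------------------------------------------------------------------
# Individual-level statistics
# ---------------------------------------------------------------------------


def asd_matrix(panel: GenotypePanel) -> pd.DataFrame:
    """Allele-sharing distance between all pairs of individuals.

    Per-site distance is the probability that one allele drawn from each
    individual differs: 0 for identical homozygotes, 0.5 when a
    heterozygote is involved (including het-het), 1 for opposite
    homozygotes.  Averaged over pairwise-complete sites.
    """
    gt = panel.gt.astype(float)
    gt[panel.gt == MISSING] = np.nan
    x = gt / 2.0
    n = panel.n_samples
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = x[:, i], x[:, j]
            ok = np.isfinite(xi) & np.isfinite(xj)
            if not ok.any():
                continue
            d = xi[ok] * (1 - xj[ok]) + (1 - xi[ok]) * xj[ok]
            mat[i, j] = mat[j, i] = d.mean()
    return pd.DataFrame(mat, index=panel.samples, columns=panel.samples)


def kinship(panel: GenotypePanel, pair: tuple, min_sites: int = 1000) -> float:
    """KING-robust kinship coefficient for one pair of individuals.

    phi = (N_het,het - 2 N_opposite-hom) / (N_het(i) + N_het(j)) over
    co-called sites; symmetric in the pair.  Emits a warning when fewer
    than ``min_sites`` co-called SNPs are available.
    """
    i, j = (panel.samples.index(s) if isinstance(s, str) else int(s) for s in pair)
    gi, gj = panel.gt[:, i], panel.gt[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < min_sites:
        warnings.warn(
            f"only {int(ok.sum())} co-called sites for pair {pair}; "
            f"kinship estimate may be unstable",
            stacklevel=2,
        )
    gi, gj = gi[ok].astype(int), gj[ok].astype(int)
    n_hh = int(np.sum((gi == 1) & (gj == 1)))
    n_opp = int(np.sum(np.abs(gi - gj) == 2))
    n_het_i = int(np.sum(gi == 1))
    n_het_j = int(np.sum(gj == 1))
    denom = n_het_i + n_het_j
    if denom == 0:
        return np.nan
    return (n_hh - 2.0 * n_opp) / denom


def kinship_matrix(panel: GenotypePanel, min_sites: int = 1000) -> pd.DataFrame:
    n = panel.n_samples
    mat = np.full((n, n), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = kinship(panel, (i, j), min_sites)
    return pd.DataFrame(mat, index=panel.samples, columns=panel.samples)


def classify_degree(phi: float) -> str:
    """Relationship degree from a kinship coefficient.

    Powers-of-two bounds, closed on the lower end: first degree
    [0.177, 0.354), second [0.0884, 0.177), third [0.0442, 0.0884); below
    that 'unrelated'; phi >= 0.354 is called 'duplicate' (monozygotic/
    same sample).  Every finite phi maps to exactly one class.
    """
    if not np.isfinite(phi):
        raise ValueError("kinship coefficient must be finite")
    for name, low in _DEGREE_BOUNDS.items():
        if phi >= low:
            return name
    return "unrelated"
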