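"""EHH-based selection scan.

Extended haplotype homozygosity (EHH) around a focal SNP measures the
probability that two randomly drawn haplotypes carrying the same focal
allele are identical over the interval from the focal SNP out to a given
map distance.  Integrating the EHH decay (trapezoidal rule, truncated when
EHH falls below a cutoff, default 0.05) gives iHH per allele; the
log-ratio of the two allelic iHH values, standardized genome-wide, is the
iHS statistic.  Rsb contrasts the site-EHH integral (iES) of the same SNP
between two populations.  Per-SNP statistics are converted to -log10
p-value scores under a standard-normal null, shifted by a tuning constant
xi, and aggregated along each chromosome with a Lindley process whose
significant excursions delimit candidate selection windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import log_ndtr

from .panels import HaplotypePanel

EHH_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------


def _group_homozygosity(hap_block: np.ndarray) -> float:
    """Probability two distinct haplotypes (rows) are identical."""
    n = hap_block.shape[0]
    if n < 2:
        return np.nan
    _, counts = np.unique(hap_block, axis=0, return_counts=True)
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def _ehh_one_side(hap: np.ndarray, rows: np.ndarray, cm: np.ndarray,
                  focal: int, step: int):
    """EHH values and map positions walking from the focal SNP outward.

    ``hap`` is the full (n_hap, n_sites) chromosome matrix and ``rows``
    selects the carrier haplotypes; the walk stops after the first marker
    whose EHH falls below EHH_CUTOFF (that marker is included, so the
    integral's last trapezoid bridges down to it).  Returns (ehh array,
    cm array) starting at the focal SNP.
    """
    n = len(rows)
    idx = [focal]
    ehh = [1.0]
    j = focal
    # incremental grouping: group id per haplotype over the growing interval
    group = np.zeros(n, dtype=np.int64)
    while True:
        j += step
        if j < 0 or j >= hap.shape[1]:
            break
        key = group * 2 + hap[rows, j]
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        e = float(np.sum(counts * (counts - 1)) / (n * (n - 1)))
        idx.append(j)
        ehh.append(e)
        if e < EHH_CUTOFF:
            break
    return np.array(ehh), cm[np.array(idx)]


def _integrate(ehh: np.ndarray, cm: np.ndarray) -> float:
    return float(np.abs(np.trapezoid(ehh, cm)))


def ehh_and_ihh(panel: HaplotypePanel, focal: int) -> dict:
    """Per-allele EHH decay curves and integrated iHH at one focal SNP.

    Returns, per focal allele a in {0, 1}: ``ehh_left``/``ehh_right``
    (arrays of (cm, EHH) pairs walking away from the focal SNP) and
    ``ihh`` (sum of both one-sided integrals).  An allele with fewer than
    two carriers has no curve (``None``) and NaN iHH.
    """
    chrom = panel.chrom[focal]
    on_chrom = np.flatnonzero(panel.chrom == chrom)
    hap = panel.hap[on_chrom].T  # (n_hap, n_sites_on_chrom)
    cm = panel.cm[on_chrom]
    focal_local = int(np.searchsorted(on_chrom, focal))
    out = {}
    for allele in (0, 1):
        rows = np.flatnonzero(hap[:, focal_local] == allele)
        if rows.size < 2:
            out[allele] = {"ehh_left": None, "ehh_right": None, "ihh": np.nan}
            continue
        el, cl = _ehh_one_side(hap, rows, cm, focal_local, -1)
        er, cr = _ehh_one_side(hap, rows, cm, focal_local, +1)
        ihh = _integrate(el, cl) + _integrate(er, cr)
        out[allele] = {
            "ehh_left": np.column_stack([cl, el]),
            "ehh_right": np.column_stack([cr, er]),
            "ihh": ihh,
        }
    return out


def _ies(hap: np.ndarray, cm: np.ndarray, focal: int) -> float:
    """Integrated site-EHH: pairwise identity over all haplotypes,
    normalised to 1 at the focal SNP, integrated both ways."""
    n = hap.shape[0]
    h0 = _group_homozygosity(hap[:, [focal]])
    if not np.isfinite(h0) or h0 == 0:
        return np.nan
    total = 0.0
    for step in (-1, +1):
        idx = [focal]
        vals = [1.0]
        j = focal
        # start groups at the focal allele so EHHS reflects the focal site
        _, group = np.unique(hap[:, focal].astype(np.int64), return_inverse=True)
        while True:
            j += step
            if j < 0 or j >= hap.shape[1]:
                break
            key = group * 2 + hap[:, j]
            _, group = np.unique(key, return_inverse=True)
            counts = np.bincount(group)
            e = float(np.sum(counts * (counts - 1)) / (n * (n - 1))) / h0
            idx.append(j)
            vals.append(e)
            if e < EHH_CUTOFF:
                break
        total += _integrate(np.array(vals), cm[np.array(idx)])
    return total


# ---------------------------------------------------------------------------
# iHS / Rsb
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    ok = np.isfinite(x)
    m, s = x[ok].mean(), x[ok].std(ddof=0)
    return (x - m) / s if s > 0 else np.full_like(x, np.nan)


def ihs(
    panel: HaplotypePanel, maf_min: float = 0.01, standardize: bool = True
) -> pd.DataFrame:
    """Standardized iHS per SNP.

    Unstandardized iHS = ln(iHH_1 / iHH_0) with allele 1 the panel's
    alternate allele (alleles are not polarised, so the sign convention is
    arbitrary but fixed).  SNPs with MAF <= ``maf_min`` are excluded;
    SNPs where either allelic iHH is zero or undefined are skipped and
    counted.  Standardization uses a single frequency bin: mean 0, SD 1
    over all retained SNPs.
    """
    freq = panel.hap.mean(axis=1)
    maf = np.minimum(freq, 1 - freq)
    keep = maf > maf_min
    uns = np.full(panel.n_sites, np.nan)
    for chrom in np.unique(panel.chrom):
        sel = panel.chrom == chrom
        hap, cm = panel.hap[sel].T, panel.cm[sel]
        base = np.flatnonzero(sel)
        for j in np.flatnonzero(keep[sel]):
            ihh = []
            for allele in (0, 1):
                rows = np.flatnonzero(hap[:, j] == allele)
                if rows.size < 2:
                    ihh.append(np.nan)
                    continue
                el, cl = _ehh_one_side(hap, rows, cm, j, -1)
                er, cr = _ehh_one_side(hap, rows, cm, j, +1)
                ihh.append(_integrate(el, cl) + _integrate(er, cr))
            ihh0, ihh1 = ihh
            if np.isfinite(ihh0) and np.isfinite(ihh1) and ihh0 > 0 and ihh1 > 0:
                uns[base[j]] = np.log(ihh1 / ihh0)
    df = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "freq_alt": freq,
            "ihs_uns": uns,
        }
    )
    df["ihs"] = _standardize(uns) if standardize else uns
    df.attrs["n_excluded_maf"] = int((~keep).sum())
    df.attrs["n_skipped_ihh"] = int(keep.sum() - np.isfinite(uns).sum())
    return df


def rsb(
    panel_x: HaplotypePanel, panel_y: HaplotypePanel, standardize: bool = True
) -> pd.DataFrame:
    """Standardized Rsb per SNP shared between two population panels.

    Rsb = ln(iES_X / iES_Y) standardized genome-wide; positive values mean
    extended haplotype homozygosity in X relative to Y.  SNPs monomorphic
    in both panels are excluded.
    """
    key_x = pd.MultiIndex.from_arrays([panel_x.chrom, panel_x.pos])
    key_y = pd.MultiIndex.from_arrays([panel_y.chrom, panel_y.pos])
    shared = key_x.intersection(key_y)
    ix = np.flatnonzero(key_x.isin(shared))
    iy = np.flatnonzero(key_y.isin(shared))
    px, py = panel_x.take_sites(ix), panel_y.take_sites(iy)
    poly = (px.hap.mean(axis=1) % 1 != 0) | (py.hap.mean(axis=1) % 1 != 0)
    uns = np.full(px.n_sites, np.nan)
    for chrom in np.unique(px.chrom):
        selx = px.chrom == chrom
        hap_x, cm_x = px.hap[selx].T, px.cm[selx]
        hap_y, cm_y = py.hap[selx].T, py.cm[selx]
        local = np.flatnonzero(poly[selx])
        base = np.flatnonzero(selx)
        for j in local:
            ies_x = _ies(hap_x, cm_x, j)
            ies_y = _ies(hap_y, cm_y, j)
            if np.isfinite(ies_x) and np.isfinite(ies_y) and ies_y > 0 and ies_x > 0:
                uns[base[j]] = np.log(ies_x / ies_y)
    df = pd.DataFrame(
        {"chrom": px.chrom, "pos": px.pos, "rsb_uns": uns}
    )
    df["rsb"] = _standardize(uns) if standardize else uns
    return df


# ---------------------------------------------------------------------------
# p-value transforms and Lindley local score
# ---------------------------------------------------------------------------


def p_transform(stat: np.ndarray, mode: str) -> np.ndarray:
    """-log10 p-value scores from a standardized statistic.

    mode 'ihs': two-sided, p = 1 - 2|Phi(x) - 0.5| = 2 Phi(-|x|);
    mode 'rsb': one-sided, p = 1 - Phi(x).
    Computed through the log-CDF for numerical stability in the far tail;
    non-finite statistics yield NaN.
    """
    x = np.asarray(stat, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    if mode == "ihs":
        out[ok] = -(np.log(2.0) + log_ndtr(-np.abs(x[ok]))) / np.log(10.0)
    elif mode == "rsb":
        out[ok] = -log_ndtr(-x[ok]) / np.log(10.0)
    else:
        raise ValueError("mode must be 'ihs' or 'rsb'")
    return out


def lindley(scores: np.ndarray) -> np.ndarray:
    """Lindley process L_i = max(0, L_{i-1} + s_i) over SNP scores."""
    out = np.empty(len(scores))
    acc = 0.0
    for i, s in enumerate(scores):
        acc = max(0.0, acc + s)
        out[i] = acc
    return out


def max_excursion_height(scores: np.ndarray) -> float:
    """Maximum Lindley excursion height, equal to the maximum over all
    contiguous SNP intervals of the interval score sum."""
    s = np.cumsum(scores)
    running_min = np.minimum.accumulate(np.concatenate([[0.0], s]))[:-1]
    return float(np.max(s - running_min, initial=0.0))


def mc_threshold(
    scores: np.ndarray, alpha: float = 0.01, n_perm: int = 1000, seed: int = 0
) -> float:
    """Monte-Carlo per-chromosome significance threshold: the (1-alpha)
    quantile of the maximal excursion height over random permutations of
    the SNP scores (breaking the spatial arrangement of the observed
    scores while keeping their distribution)."""
    rng = np.random.default_rng(seed)
    s = np.asarray(scores, dtype=float)
    s = s[np.isfinite(s)]
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        maxima[k] = max_excursion_height(rng.permutation(s))
    return float(np.quantile(maxima, 1 - alpha))


def analytic_threshold(scores: np.ndarray, alpha: float = 0.01) -> float:
    """Gumbel-type analytic approximation of the excursion threshold.

    For i.i.d. scores with negative mean, the maximal excursion height M
    over n SNPs satisfies approximately P(M > x) = 1 - exp(-n K e^{-lam x})
    with lam the positive root of E[e^{lam X}] = 1 (estimated on the
    empirical score distribution) and K approximated as 1.  Solving for
    the 1-alpha quantile gives x = log(-n K / log(1 - alpha)) / lam.
    """
    s = np.asarray(scores, dtype=float)
    s = s[np.isfinite(s)]
    if s.mean() >= 0:
        raise ValueError("scores must have negative mean for the Gumbel bound")

    def mgf_minus_one(lam):
        return np.mean(np.exp(lam * s)) - 1.0

    hi = 1.0
    while mgf_minus_one(hi) < 0 and hi < 1e3:
        hi *= 2.0
    lam = brentq(mgf_minus_one, 1e-9, hi)
    n = len(s)
    return float(np.log(-n / np.log(1.0 - alpha)) / lam)


@dataclass
class Excursion:
    start_idx: int
    end_idx: int
    peak_idx: int
    peak_score: float


def excursions(scores: np.ndarray) -> list[Excursion]:
    """Maximal positive excursions of the Lindley process.

    An excursion runs from the first SNP where L rises above zero to the
    last SNP before L returns to zero (or the chromosome end); the peak is
    the leftmost argmax of L within the excursion.
    """
    ll = lindley(scores)
    out = []
    start = None
    for i, v in enumerate(ll):
        if v > 0 and start is None:
            start = i
        elif v == 0 and start is not None:
            seg = ll[start:i]
            peak = start + int(np.argmax(seg))
            out.append(Excursion(start, i - 1, peak, float(ll[peak])))
            start = None
    if start is not None:
        seg = ll[start:]
        peak = start + int(np.argmax(seg))
        out.append(Excursion(start, len(ll) - 1, peak, float(ll[peak])))
    return out


def local_score(
    pscores: np.ndarray,
    pos: np.ndarray,
    chrom: str,
    xi: float = 2.0,
    alpha: float = 0.01,
    threshold_mode: str = "mc",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Candidate selection windows on one chromosome.

    SNP score = pscore - xi (pscore on the -log10 p scale); the Lindley
    process of these scores is segmented into excursions and those whose
    peak exceeds the chromosome's (1 - alpha) significance threshold are
    reported.  Window bounds are the excursion's first/last SNP positions.
    NaN pscores are treated as fully non-significant (p = 1, score = -xi).
    """
    pscores = np.asarray(pscores, dtype=float)
    scores = np.where(np.isfinite(pscores), pscores, 0.0) - xi
    pos = np.asarray(pos)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    if threshold_mode == "mc":
        thr = mc_threshold(scores, alpha=alpha, n_perm=n_perm, seed=seed)
    elif threshold_mode == "analytic":
        thr = analytic_threshold(scores, alpha=alpha)
    else:
        raise ValueError("threshold_mode must be 'mc' or 'analytic'")
    rows = []
    for exc in excursions(scores):
        if exc.peak_score > thr:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[exc.start_idx]),
                    "end": int(pos[exc.end_idx]),
                    "n_snps": exc.end_idx - exc.start_idx + 1,
                    "peak_pos": int(pos[exc.peak_idx]),
                    "peak_score": exc.peak_score,
                    "threshold": thr,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_snps", "peak_pos", "peak_score", "threshold",
        ],
    )
    df.attrs["threshold"] = thr
    return df


def genome_local_score(stat_df: pd.DataFrame, score_col: str, **kwargs) -> pd.DataFrame:
    """Run :func:`local_score` per chromosome on a per-SNP score table."""
    parts = []
    for chrom, grp in stat_df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        parts.append(
            local_score(
                grp[score_col].to_numpy(), grp["pos"].to_numpy(), str(chrom), **kwargs
            )
        )
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_snps", "peak_pos",
                     "peak_score", "threshold"]
        )
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def annotate_regions(windows: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach the nearest gene to each window's peak.

    ``genes`` columns: chrom, start, end (0-based half-open), name.
    Distance is 0 when the peak lies inside the gene, else the gap to the
    closer gene boundary in kb.  Ties (two equidistant genes) report both
    names joined by ';' and set ``ambiguous``.
    """
    out = windows.copy()
    nearest, dist_kb, ambig = [], [], []
    for _, w in windows.iterrows():
        sub = genes[genes["chrom"] == w["chrom"]]
        if sub.empty:
            nearest.append("")
            dist_kb.append(np.nan)
            ambig.append(False)
            continue
        peak0 = int(w["peak_pos"]) - 1  # to 0-based
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        inside = (peak0 >= starts) & (peak0 < ends)
        gaps = np.where(
            inside, 0, np.where(peak0 < starts, starts - peak0, peak0 - (ends - 1))
        )
        best = gaps.min()
        hits = sub["name"].to_numpy()[gaps == best]
        nearest.append(";".join(hits))
        dist_kb.append(best / 1000.0)
        ambig.append(len(hits) > 1)
    out["nearest_gene"] = nearest
    out["gene_distance_kb"] = dist_kb
    out["ambiguous"] = ambig
    return out
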