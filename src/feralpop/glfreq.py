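"""Allele-frequency and site-frequency-spectrum estimation from genotype
likelihoods.

Allele frequencies are maximum-likelihood estimates under Hardy–Weinberg
genotype priors, obtained with an EM algorithm operating on the (linear,
renormalised) genotype likelihoods.  The probabilistic SFS sums, per site,
the probability of each possible derived-allele count over all genotype
configurations of the population sample; the implementation uses a
probability-generating-function convolution whose result equals the full
3^n enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel, derived_is_alt, polarized_mask

#: segregating-site band: strict inequalities on the alt-allele frequency
AF_LOWER = 0.001
AF_UPPER = 0.999


@dataclass
class EMResult:
    af: float
    converged: bool
    n_iter: int
    loglik: float


def _hwe_priors(p: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def em_allele_frequency(
    site_likelihoods: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> EMResult:
    """EM estimate of the alt-allele frequency at one site.

    Parameters
    ----------
    site_likelihoods : (n_ind, 3) array
        Linear-scale genotype likelihoods (any positive scaling per
        individual); rows that are all zero or non-finite are dropped.
    tol : convergence threshold on \\|ΔAF\\| between iterations.

    The marginal log-likelihood sum_i log sum_g GL_i(g) P(g | AF) is
    non-decreasing across iterations (EM guarantee, asserted in tests).
    """
    gl = np.asarray(site_likelihoods, dtype=float)
    if gl.ndim != 2 or gl.shape[1] != 3:
        raise ValueError("site_likelihoods must be (n_ind, 3)")
    keep = np.isfinite(gl).all(axis=1) & (gl.sum(axis=1) > 0)
    gl = gl[keep]
    if gl.shape[0] == 0:
        raise ValueError("no individual with informative likelihoods")
    gl = gl / gl.sum(axis=1, keepdims=True)
    n = gl.shape[0]

    # GL-weighted naive initial estimate
    p = float((gl @ np.array([0.0, 0.5, 1.0])).mean())
    p = min(max(p, 1e-9), 1 - 1e-9)
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prior = _hwe_priors(np.array(p))
        w = gl * prior
        norm = w.sum(axis=1, keepdims=True)
        loglik = float(np.log(norm).sum())
        w = w / norm
        p_new = float((w[:, 1] + 2.0 * w[:, 2]).sum() / (2.0 * n))
        if abs(p_new - p) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return EMResult(af=p, converged=converged, n_iter=it, loglik=loglik)


def em_allele_frequencies(
    panel: GenotypePanel, pop: str, tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Vectorised per-site EM alt-allele frequencies for one population.

    Missing individuals are dropped from a site's EM.  Sites where every
    individual is missing return NaN.
    """
    idx = panel.sample_indices(pop)
    gp = panel.gp[:, idx, :]
    miss = panel.gt[:, idx] == MISSING
    n_obs = (~miss).sum(axis=1).astype(float)

    w_informative = np.where(miss[:, :, None], 0.0, gp)
    dose = w_informative @ np.array([0.0, 0.5, 1.0])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose.sum(axis=1) / np.maximum(n_obs, 1.0)
    p = np.clip(p, 1e-9, 1 - 1e-9)

    active = n_obs > 0
    for _ in range(max_iter):
        prior = _hwe_priors(p)  # (n_sites, 3)
        w = gp * prior[:, None, :]
        norm = w.sum(axis=2, keepdims=True)
        w = np.where(miss[:, :, None], 0.0, w / np.maximum(norm, 1e-300))
        p_new = (w[:, :, 1] + 2.0 * w[:, :, 2]).sum(axis=1) / np.maximum(
            2.0 * n_obs, 1.0
        )
        moved = np.abs(p_new - p) >= tol
        p = np.where(active, p_new, p)
        if not np.any(moved & active):
            break
    p = np.where(n_obs > 0, p, np.nan)
    return p


def polarize_site(outgroup_dosages) -> int | None:
    """Ancestral-allele call from outgroup genotypes at one site.

    ``outgroup_dosages`` are alt-allele dosages (0/1/2, -1 missing) for up
    to four outgroup individuals.  Returns 0 (ref ancestral), 1 (alt
    ancestral) or None (unassigned).  The call is made when all non-missing
    outgroups are homozygous for the same allele and at most one outgroup
    is missing.
    """
    d = np.asarray(outgroup_dosages, dtype=int)
    if d.size == 0 or d.size > 4:
        raise ValueError("expected 1-4 outgroup genotypes")
    missing = d == MISSING
    if missing.sum() > 1:
        return None
    obs = d[~missing]
    if obs.size == 0:
        return None
    if np.all(obs == 0):
        return 0
    if np.all(obs == 2):
        return 1
    return None


def polarize_sites(outgroup_dosages: np.ndarray) -> np.ndarray:
    """Vectorised :func:`polarize_site` over a (n_sites, n_outgroups)
    dosage matrix; returns int array with -1 for unassigned."""
    d = np.asarray(outgroup_dosages, dtype=int)
    missing = d == MISSING
    ok_missing = missing.sum(axis=1) <= 1
    n_obs = (~missing).sum(axis=1)
    all_ref = np.where(missing, 0, d).sum(axis=1) == 0
    all_alt = np.where(missing, 2, d).sum(axis=1) == 2 * d.shape[1]
    out = np.full(d.shape[0], -1, dtype=int)
    out[ok_missing & (n_obs > 0) & all_ref] = 0
    out[ok_missing & (n_obs > 0) & all_alt] = 1
    return out


def derived_frequencies(af: np.ndarray, alt_is_derived: np.ndarray) -> np.ndarray:
    """Flip alt-allele frequencies into derived-allele frequencies."""
    return np.where(alt_is_derived, af, 1.0 - af)


def count_segregating_fixed(
    af: np.ndarray,
    derived_af: np.ndarray | None = None,
    polarized: np.ndarray | None = None,
    polarized_only_denominator: bool = True,
) -> dict:
    """Segregating and fixed-derived site counts for one population.

    segregating: sites with AF_LOWER < AF < AF_UPPER (strict).
    fixed-derived: the proportion of polarised sites whose derived-allele
    frequency exceeds AF_UPPER, extrapolated to the total site count.
    ``polarized_only_denominator`` controls whether that proportion uses
    polarised sites only (default) or all sites as denominator.
    """
    af = np.asarray(af, dtype=float)
    valid = np.isfinite(af)
    segregating = int(np.sum((af > AF_LOWER) & (af < AF_UPPER) & valid))
    out = {"n_sites": int(valid.sum()), "segregating": segregating}
    if derived_af is not None and polarized is not None:
        derived_af = np.asarray(derived_af, dtype=float)
        pol = np.asarray(polarized, dtype=bool) & np.isfinite(derived_af)
        n_pol = int(pol.sum())
        n_fixed_pol = int(np.sum(derived_af[pol] > AF_UPPER))
        denom = n_pol if polarized_only_denominator else int(valid.sum())
        prop = n_fixed_pol / denom if denom else np.nan
        out.update(
            n_polarized=n_pol,
            fixed_derived_observed=n_fixed_pol,
            fixed_derived_proportion=prop,
            fixed_derived_extrapolated=prop * int(valid.sum()),
        )
    return out


def site_sfs_probabilities(gp: np.ndarray) -> np.ndarray:
    """Per-site probabilities of k = 0..2n derived copies.

    ``gp`` is a (n_sites, n_ind, 3) genotype-probability array ordered as
    (hom-ancestral, het, hom-derived).  Each individual contributes the
    generating polynomial gp0 + gp1 z + gp2 z^2; the product over
    individuals gives the distribution of the derived-allele count.  Equals
    the brute-force sum over all 3^n genotype configurations.
    """
    gp = np.asarray(gp, dtype=float)
    n_sites, n_ind, _ = gp.shape
    coef = np.zeros((n_sites, 2 * n_ind + 1))
    coef[:, 0] = 1.0
    deg = 0
    for i in range(n_ind):
        new = np.zeros_like(coef)
        for g in range(3):
            new[:, g : deg + g + 1] += coef[:, : deg + 1] * gp[:, i, g : g + 1]
        coef = new
        deg += 2
    return coef


def probabilistic_sfs(panel: GenotypePanel, pop: str, alt_is_derived: np.ndarray,
                      polarized: np.ndarray) -> np.ndarray:
    """Population SFS vector: expected number of sites carrying k derived
    copies, for k = 1..2n-1.

    Restricted to polarised sites with no missing genotype in the
    population.  Monomorphic mass (k = 0 and k = 2n) is excluded.
    """
    sub = panel.for_population(pop)
    keep = np.asarray(polarized, dtype=bool) & ~(sub.gt == MISSING).any(axis=1)
    gp = sub.gp[keep]
    flip = ~np.asarray(alt_is_derived, dtype=bool)[keep]
    gp = np.where(flip[:, None, None], gp[:, :, ::-1], gp)
    per_site = site_sfs_probabilities(gp)
    return per_site.sum(axis=0)[1:-1]


def expected_heterozygosity(af: np.ndarray, n_diploids: np.ndarray | int) -> float:
    """Mean unbiased expected heterozygosity 2p(1-p) * 2n/(2n-1) across
    sites; ``n_diploids`` may vary per site (e.g. with missingness)."""
    af = np.asarray(af, dtype=float)
    n = np.broadcast_to(np.asarray(n_diploids, dtype=float), af.shape)
    ok = np.isfinite(af) & (n * 2 > 1)
    if not np.any(ok):
        return 0.0
    h = 2.0 * af[ok] * (1.0 - af[ok]) * (2.0 * n[ok]) / (2.0 * n[ok] - 1.0)
    return float(h.mean())


def population_frequency_table(
    panel: GenotypePanel,
    variants: pd.DataFrame | None = None,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-site table of EM alt-allele (and, when polarised, derived-allele)
    frequencies for every population in the panel."""
    df = pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos})
    if variants is not None:
        pol = polarized_mask(variants)
        # derived allele is alt exactly when the ancestral call equals ref
        alt_derived = derived_is_alt(variants)
    for pop in panel.populations:
        af = em_allele_frequencies(panel, pop, tol=tol)
        df[f"af_{pop}"] = af
        if variants is not None:
            fder = np.where(pol, derived_frequencies(af, alt_derived), np.nan)
            df[f"daf_{pop}"] = fder
    return df
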