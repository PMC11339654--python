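"""Genetic offset: environmental PCA, gene-environment association (GEA)
coefficients, and the offset / environmental-distance statistics.

The genetic offset between an environment e_j and a reference environment
e_ref is the quadratic form

    GO_j = (1/n_snp) (e_j - e_ref)' B'B (e_j - e_ref)

where B (n_snp x n_pc) holds per-SNP regression coefficients of population
allele frequencies on the environmental principal components.  It weights
environmental distance by how strongly each PC axis is associated with the
structuring of allele frequencies, and is read as expected maladaptation of
a population moved from e_j to e_ref.  The unweighted counterpart is the
Euclidean distance delta_j = sqrt((1/n_e) ||e_j - e_ref||^2).

The coefficient estimator here is a per-SNP (optionally ridge-penalised)
linear regression of population allele frequencies on the standardized PC
scores; correctness is defined by recovery of simulated truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EnvDesign:
    """Environmental PCA design: training covariates, loadings, scores,
    and (once estimated) the SNP x PC coefficient matrix B."""

    covariate_names: list
    pop_names: list
    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_cov, n_pc), orthonormal columns
    scores: np.ndarray  # (n_pop, n_pc)
    variance_explained: np.ndarray  # per retained PC, fraction of total
    b_matrix: np.ndarray | None = None

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def project(self, covariates: np.ndarray) -> np.ndarray:
        """Project new covariate rows onto the training PC axes using the
        training centering/scaling.  Training rows reproduce their own
        scores."""
        x = (np.asarray(covariates, dtype=float) - self.mean) / self.scale
        return x @ self.loadings


def env_pca(
    covariates: pd.DataFrame | np.ndarray,
    n_keep: int = 7,
    variance_threshold: float | None = None,
) -> EnvDesign:
    """PCA of centered-and-scaled environmental covariates.

    ``n_keep`` PCs are retained (default 7); alternatively
    ``variance_threshold`` retains the smallest number of PCs whose
    cumulative variance-explained reaches the threshold.  Constant
    covariate columns are dropped with a warning.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        pop_names = list(covariates.index)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        names = [f"cov{i}" for i in range(x.shape[1])]
        pop_names = [f"pop{i}" for i in range(x.shape[0])]
    if x.shape[0] < 2:
        raise ValueError("need at least two populations")
    sd = x.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"dropping {int(const.sum())} constant covariate column(s)",
            stacklevel=2,
        )
        x = x[:, ~const]
        names = [n for n, c in zip(names, const) if not c]
        sd = sd[~const]
    mean = x.mean(axis=0)
    xs = (x - mean) / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    var = s**2 / np.sum(s**2)
    if variance_threshold is not None:
        n_keep = int(np.searchsorted(np.cumsum(var), variance_threshold) + 1)
    n_keep = min(n_keep, len(s))
    return EnvDesign(
        covariate_names=names,
        pop_names=pop_names,
        mean=mean,
        scale=sd,
        loadings=vt[:n_keep].T,
        scores=xs @ vt[:n_keep].T,
        variance_explained=var[:n_keep],
    )


def estimate_gea_coefficients(
    pop_freqs: np.ndarray,
    env_scores: np.ndarray,
    ridge: float = 0.0,
) -> np.ndarray:
    """Per-SNP linear GEA coefficients B (n_snp x n_pc).

    Regresses each SNP's population allele frequencies (rows of
    ``pop_freqs``: n_snp x n_pop) on the standardized PC scores
    (n_pop x n_pc) with an intercept; ``ridge`` adds an L2 penalty on the
    slope coefficients.  Near-collinear score matrices force a small ridge
    on with a warning.
    """
    f = np.asarray(pop_freqs, dtype=float)
    e = np.asarray(env_scores, dtype=float)
    n_pop, n_pc = e.shape
    if f.shape[1] != n_pop:
        raise ValueError("pop_freqs columns must match env_scores rows")
    if n_pop < n_pc + 2:
        raise ValueError("need at least n_pc + 2 populations")
    es = (e - e.mean(axis=0)) / np.where(e.std(axis=0) > 0, e.std(axis=0), 1.0)
    x = np.column_stack([np.ones(n_pop), es])
    xtx = x.T @ x
    if ridge == 0.0 and np.linalg.cond(xtx) > 1e10:
        warnings.warn("collinear PC scores; forcing ridge=1e-6", stacklevel=2)
        ridge = 1e-6
    pen = np.eye(n_pc + 1) * ridge
    pen[0, 0] = 0.0  # never penalise the intercept
    coefs = np.linalg.solve(xtx + pen, x.T @ f.T)
    return coefs[1:].T  # (n_snp, n_pc)


def genetic_offset(b_matrix: np.ndarray, e_j: np.ndarray, e_ref: np.ndarray) -> float:
    """GO = (1/n_snp) d' B'B d with d = e_j - e_ref; non-negative and
    symmetric in the two environments."""
    b = np.asarray(b_matrix, dtype=float)
    d = np.asarray(e_j, dtype=float) - np.asarray(e_ref, dtype=float)
    if d.shape[0] != b.shape[1]:
        raise ValueError(
            f"environment dimension {d.shape[0]} does not match "
            f"B columns {b.shape[1]}"
        )
    bd = b @ d
    return float(bd @ bd / b.shape[0])


def environmental_distance(e_j, e_ref, n_pcs: int | None = None) -> float:
    """delta = sqrt((1/n_e) ||e_j - e_ref||^2), the per-axis-normalised
    Euclidean distance between environmental PC vectors."""
    d = np.asarray(e_j, dtype=float) - np.asarray(e_ref, dtype=float)
    ne = n_pcs if n_pcs is not None else d.shape[0]
    return float(np.sqrt(d @ d / ne))


def offset_table(
    design: EnvDesign, b_matrix: np.ndarray, ref_pop: str
) -> pd.DataFrame:
    """GO and delta of every training population relative to ``ref_pop``."""
    ref = design.scores[design.pop_names.index(ref_pop)]
    rows = []
    for name, e in zip(design.pop_names, design.scores):
        rows.append(
            {
                "pop": name,
                "go": genetic_offset(b_matrix, e, ref),
                "delta": environmental_distance(e, ref),
            }
        )
    return pd.DataFrame(rows)


def go_surface(
    grid: pd.DataFrame,
    design: EnvDesign,
    b_matrix: np.ndarray,
    e_ref: np.ndarray,
    rescale: bool = True,
) -> pd.DataFrame:
    """Genetic offset over a grid of locations.

    ``grid`` columns: ``lon``, ``lat``, then the training covariate set.
    Each row is projected with the training loadings; with ``rescale``
    the projected scores are standardised exactly as the training scores
    were (same centering/scaling, which the projection already applies).
    Rows with any missing covariate are skipped and counted in the
    ``skipped`` attribute of the returned frame.
    """
    missing_cov = [c for c in design.covariate_names if c not in grid.columns]
    if missing_cov:
        raise ValueError(f"grid lacks covariate columns: {missing_cov}")
    cov = grid[design.covariate_names].to_numpy(dtype=float)
    ok = np.isfinite(cov).all(axis=1)
    scores = design.project(cov[ok])
    go = np.array([genetic_offset(b_matrix, e, e_ref) for e in scores])
    out = pd.DataFrame(
        {
            "cell": np.flatnonzero(ok),
            "lon": grid.loc[ok, "lon"].to_numpy(),
            "lat": grid.loc[ok, "lat"].to_numpy(),
            "go": go,
        }
    )
    out.attrs["skipped"] = int((~ok).sum())
    return out
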