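import numpy as np
import pytest
from hypothesis import settings

import feralpop as fp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def desk_cfg():
    """Desk-scale founder-bottleneck scenario used across the suite."""
    return fp.SimConfig(
        n_sites=2000,
        n_chromosomes=2,
        chrom_length=3e6,
        source_size=2000,
        t_divergence=500,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(desk_cfg):
    return fp.simulate_cohort(desk_cfg)


@pytest.fixture(scope="session")
def gpanel(desk_cfg, cohort):
    hap, _, _ = cohort
    return fp.simdata.emit_sequencing_data(hap, desk_cfg)


def certain_panel(gt, pops, chrom=None, pos=None):
    """GenotypePanel with fully certain genotype probabilities from a
    dosage matrix (n_sites, n_ind)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape
    gp = np.full((n_sites, n_ind, 3), 0.0)
    for g in range(3):
        gp[:, :, g] = gt == g
    gp[gt == -1] = 1 / 3
    if chrom is None:
        chrom = np.array(["1"] * n_sites, dtype=object)
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    return fp.GenotypePanel(
        chrom=chrom,
        pos=np.asarray(pos),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["C"] * n_sites, dtype=object),
        gt=gt,
        gp=gp,
        samples=[f"S{i}" for i in range(n_ind)],
        pops=np.asarray(pops),
    )
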