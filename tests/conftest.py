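"""Shared fixtures: small hand-built genotype matrices and module-scoped
simulated datasets (simulation is the expensive part, so scan-scale data
are built once per session)."""

import logging

import numpy as np
import pytest

from triadscan.io import GenotypeMatrix, PopulationAssignment, Triad
from triadscan.simulate import (DomesticationConfig, SimulationConfig,
                                sample_populations, simulate_domestication,
                                simulate_genome)

logging.getLogger("triadscan").setLevel(logging.WARNING)

TRIAD = Triad("P1", "P2", "P3", "OUT")


def make_matrix(dosages, samples=None, chrom="1", start=0, step=1,
                ref="A", alt="C"):
    """GenotypeMatrix from a (n_sites, n_samples) dosage list."""
    d = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samp = d.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samp)]
    pos = np.arange(start, start + step * n_sites, step)
    return GenotypeMatrix(np.array([chrom] * n_sites), pos, d, samples,
                          np.array([ref] * n_sites), np.array([alt] * n_sites))


def random_matrix(rng, n_sites=30, samples_per_pop=3, p_missing=0.1):
    """Random 4-population matrix with the triad role layout of conftest.TRIAD."""
    pops = ["P1", "P2", "P3", "OUT"]
    samples = [f"{p}_{i}" for p in pops for i in range(samples_per_pop)]
    d = rng.integers(0, 3, size=(n_sites, len(samples))).astype(np.int8)
    d[rng.random(d.shape) < p_missing] = -1
    g = make_matrix(d, samples=samples)
    mapping = {s: s.rsplit("_", 1)[0] for s in samples}
    return g, PopulationAssignment(mapping, TRIAD)


@pytest.fixture(scope="session")
def calib_sim():
    """No-admixture, no-tip-noise genome: E[d_XY(P1,P2)] = 2·t12 exactly."""
    cfg = SimulationConfig(n_windows=500, theta_tip=0.0, admix_fraction=0.0,
                           p_ils=0.0, t12=0.01, seed=11)
    g, truth, seqs, genes = simulate_genome(cfg)
    return cfg, g, truth


@pytest.fixture(scope="session")
def ils_sim():
    """No gene flow but with discordant (lineage-sorting) windows, so
    ABBA/BABA sums are non-degenerate and genome-wide D is testable."""
    cfg = SimulationConfig(n_windows=500, theta_tip=0.0, admix_fraction=0.0,
                           p_ils=0.2, t12=0.01, seed=12)
    g, truth, seqs, genes = simulate_genome(cfg)
    return cfg, g, truth


@pytest.fixture(scope="session")
def pulse_sim():
    """1000 windows, 10% introgressed (t_admix = 0.2·t12), plus lineage
    sorting: the recovery benchmark for the joint outlier rule."""
    cfg = SimulationConfig(n_windows=1000, admix_fraction=0.1, t_admix=0.002,
                           t12=0.01, p_ils=0.2, seed=4)
    g, truth, seqs, genes = simulate_genome(cfg)
    return cfg, g, truth, genes


@pytest.fixture(scope="session")
def dom_sim():
    """Case-control sweep panel: 50 genes, 3 sweeps, 6/26 haplotypes."""
    cfg = DomesticationConfig(seed=5)
    g, design, truth, seqs, genes = simulate_domestication(cfg)
    return cfg, g, design, truth, seqs, genes


@pytest.fixture()
def pops_for(request):
    def _make(cfg):
        return PopulationAssignment(sample_populations(cfg), TRIAD)
    return _make
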