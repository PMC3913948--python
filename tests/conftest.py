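import numpy as np
import pytest

from snpladder import qc
from snpladder import simdata as sd


@pytest.fixture(scope="session")
def small_population():
    """A small three-chromosome population with the default demography."""
    cfg = sd.SimConfig(
        n_chromosomes=3,
        chrom_length_bp=50_000_000,
        n_markers_total=1200,
        ancestral_generations=40,
        seed=101,
    )
    panel, mmap = sd.simulate_haplotypes(cfg)
    return panel, mmap


@pytest.fixture(scope="session")
def small_cohort(small_population):
    panel, mmap = small_population
    G = sd.sample_genotypes(panel, 120, seed=202)
    return G, mmap


@pytest.fixture(scope="session")
def filtered_cohort(small_cohort):
    G, mmap = small_cohort
    Gf, mm, report = qc.apply_filters(G, mmap, qc.QCConfig())
    return Gf, mm, report


def tiny_map(positions_bp, chrom=None):
    """MarkerMap helper for hand-built cases."""
    positions_bp = np.asarray(positions_bp, dtype=np.int64)
    if chrom is None:
        chrom = np.ones(len(positions_bp), dtype=np.int64)
    return sd.MarkerMap(
        marker_id=np.array([f"m{i}" for i in range(len(positions_bp))]),
        chromosome=np.asarray(chrom, dtype=np.int64),
        position_bp=positions_bp,
    )
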