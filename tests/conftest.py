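import numpy as np
import pytest

from methyldmr.genomic_io import GenomicInterval
from methyldmr.medip import WindowCountMatrix
from methyldmr.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    """A compact two-chromosome study design used across module tests."""
    return SimulationConfig(
        seed=7, n_chroms=2, chrom_length=120_000, n_dmrs=10, n_genes=20, n_repeats=150
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_matrix(counts, n_case=None, library_sizes=None, window=200, chrom="chr1"):
    """Build a WindowCountMatrix from a counts array (windows x samples)."""
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    if n_case is None:
        n_case = n_samples // 2
    sample_ids = [f"C{i}" for i in range(n_case)] + [f"Y{i}" for i in range(n_samples - n_case)]
    groups = {s: s[0] for s in sample_ids}
    windows = [
        GenomicInterval(chrom, i * window, (i + 1) * window) for i in range(counts.shape[0])
    ]
    if library_sizes is None:
        library_sizes = np.full(n_samples, max(counts.sum() / n_samples, 1.0))
    return WindowCountMatrix(windows, counts, sample_ids, groups, np.asarray(library_sizes, float))
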