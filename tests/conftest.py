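import numpy as np
import pandas as pd
import pytest

from topodyn import SimulationSpec, simulate_timecourse
from topodyn.genome_model import ContactMatrix, GeneCatalog, IntervalSet, LoopSet


@pytest.fixture(scope="session")
def default_bundle():
    """The standard toy study: 2 x 20 Mb, 5 timepoints, seed 1."""
    return simulate_timecourse(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def small_spec():
    """Half-size genome for fast tests that only need structure, not power."""
    return SimulationSpec(
        chromsizes={"chr1": 10_000_000, "chr2": 10_000_000},
        n_genes_per_chrom=80,
        n_background_loops=40,
        n_hubs_stable=1,
        n_hubs_gained=1,
        n_hubs_lost=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return simulate_timecourse(small_spec)


def random_symmetric_counts(rng, n, lam=5.0):
    upper = np.triu(rng.poisson(lam, (n, n))).astype(float)
    return upper + np.triu(upper, 1).T


def make_intervals(rows, chromsizes=None):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), chromsizes)


def make_loops(rows):
    return LoopSet(
        pd.DataFrame(rows, columns=["chrom", "startA", "endA", "startB", "endB"])
    )


def make_genes(rows):
    return GeneCatalog(
        pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand", "biotype"])
    )
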