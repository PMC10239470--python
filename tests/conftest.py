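"""Shared fixtures: small, fast synthetic study instances.

Session-scoped fixtures cache the expensive generated objects (contact maps,
full-scale landscapes) so the planted-truth recovery tests share them.
"""

import numpy as np
import pandas as pd
import pytest

from chromrewire import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    SimConfig,
    simulate_contact_map,
    simulate_landscape,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def landscape(default_config):
    return simulate_landscape(default_config)


@pytest.fixture(scope="session")
def contact_maps(default_config):
    control = simulate_contact_map(default_config, "control")
    mutant = simulate_contact_map(default_config, "mutant", loops=control.loops)
    return control, mutant


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced scale for pipeline smoke tests: one 5 Mb chromosome."""
    return SimConfig(
        seed=7,
        n_chroms=1,
        chrom_length=5_000_000,
        n_genes=60,
        n_peaks=600,
        n_loops=30,
        loop_max_sep_bins=80,
    )


def make_genes(specs):
    """specs: iterable of (gene_id, chrom, strand, tss, start, end)."""
    return [
        GeneAnnotation(g, c, s, t, GenomicInterval(c, a, b)) for g, c, s, t, a, b in specs
    ]


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=1_000_000, max_len=5_000):
    rows = []
    for k in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        rows.append((chrom, start, start + length))
    return PeakSet.from_intervals(rows, ids=[f"p{k}" for k in range(n)])
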