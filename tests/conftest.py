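"""Shared fixtures: small simulated populations and call sets.

Everything is generated programmatically and seeded; nothing is read from
disk.
"""

import numpy as np
import pytest

from hybridscape import RecombMap, SimConfig, simulate_hybrid_population, tracts_to_calls


@pytest.fixture(scope="session")
def small_map():
    return RecombMap.uniform({"chr1": 20_000_000, "chr2": 20_000_000}, 1.0, node_spacing_bp=10_000)


@pytest.fixture(scope="session")
def small_pop(small_map):
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length_bp=20_000_000,
        recomb_map=small_map,
        N_hybrid=120,
        p0=0.76,
        t_admix=40,
        seed=42,
    )
    return simulate_hybrid_population(cfg)


@pytest.fixture(scope="session")
def small_calls(small_pop, small_map):
    sites = {c: np.arange(10_000, small_map.chrom_length(c) + 1, 10_000) for c in small_map.chroms}
    return tracts_to_calls(small_pop, sites, minor_parent=1)
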