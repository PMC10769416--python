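"""Power and false-positive calibration of the shared-desert pipeline.

Runs paired, independently formed simulated hybrid populations whose
demography mirrors the inferred histories of the two field populations:
population A with initial minor-parent ancestry 0.24 and 137 generations of
admixture, population B with 0.12 and 263 generations, both of size 1000
with the inferred (very low) migration rates, sampled at 69 and 242
individuals.  The desk-scale genome is two 25 Mb chromosomes with a uniform
1 cM/Mb map carrying map points every 10 kb and ancestry-informative markers
every 10 kb.

``shared_desert_power`` measures how often a locus under additive selection
against minor ancestry in both populations (default s = 0.05) lands inside a
detected shared minor-parent ancestry desert; ``neutral_shared_deserts``
measures the background rate of shared deserts with no selection at all.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .callset import AncestryCallSet
from .maps import RecombMap
from .outliers import _detect_runs, merge_and_filter, population_windows, shared_regions
from .simulate import SimConfig, simulate_replicate_pair

__all__ = [
    "study_recomb_map",
    "paired_population_configs",
    "shared_deserts_for_pair",
    "shared_desert_power",
    "neutral_shared_deserts",
]

CHROM_LENGTH_BP = 25_000_000
N_CHROMOSOMES = 2
MARKER_SPACING_BP = 10_000
SELECTED_LOCUS = ("chr1", 12_500_000)
SAMPLE_A, SAMPLE_B = 69, 242


def study_recomb_map() -> RecombMap:
    lengths = {f"chr{i + 1}": CHROM_LENGTH_BP for i in range(N_CHROMOSOMES)}
    return RecombMap.uniform(lengths, rate_cm_per_mb=1.0, node_spacing_bp=10_000)


def paired_population_configs(N_hybrid: int = 1000) -> tuple[SimConfig, SimConfig]:
    """Two demographies near the inferred MAP regimes of the field
    populations (minor ancestry 0.24 / 0.12, ages 137 / 263 generations,
    migration rates of order 1e-4)."""
    rmap = study_recomb_map()
    a = SimConfig(
        n_chromosomes=N_CHROMOSOMES,
        chrom_length_bp=CHROM_LENGTH_BP,
        recomb_map=rmap,
        N_hybrid=N_hybrid,
        p0=0.76,
        t_admix=137,
        m1=4e-5,
        m2=1.7e-4,
    )
    b = SimConfig(
        n_chromosomes=N_CHROMOSOMES,
        chrom_length_bp=CHROM_LENGTH_BP,
        recomb_map=rmap,
        N_hybrid=N_hybrid,
        p0=0.88,
        t_admix=263,
        m1=4e-5,
        m2=2.8e-4,
    )
    return a, b


def shared_deserts_for_pair(
    callsA: AncestryCallSet,
    callsB: AncestryCallSet,
    recomb_map: RecombMap,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full shared-desert pipeline for one replicate pair: per-population
    detection at the 5% site / 10% window tails in 0.05 cM windows, 50 kb
    merging, standard filters, >= 1 bp overlap."""
    regions = []
    for calls in (callsA, callsB):
        pw = population_windows(calls, recomb_map)
        regions.append(merge_and_filter(_detect_runs(pw, "desert")))
    shared = shared_regions(regions[0], regions[1])
    return regions[0], regions[1], shared


def _run_pair(configA, configB, loci, seed_pair):
    return simulate_replicate_pair(
        configA,
        configB,
        loci,
        seedA=int(seed_pair[0]),
        seedB=int(seed_pair[1]),
        site_spacing_bp=MARKER_SPACING_BP,
        n_sample_A=SAMPLE_A,
        n_sample_B=SAMPLE_B,
    )


def _pair_seeds(seed, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 2, size=(n, 2)) + np.array([0, 1])


def shared_desert_power(
    n_replicates: int = 100,
    s: float = 0.05,
    seed: Optional[int] = None,
    N_hybrid: int = 1000,
) -> dict:
    """Fraction of replicate pairs in which the shared selected locus falls
    inside a detected shared minor-parent ancestry desert."""
    configA, configB = paired_population_configs(N_hybrid)
    configA.selection_model = configB.selection_model = "directional"
    loci = [(*SELECTED_LOCUS, s)]
    rmap = configA.recomb_map
    chrom, pos = SELECTED_LOCUS
    hits = 0
    for seed_pair in _pair_seeds(seed, n_replicates):
        callsA, callsB = _run_pair(configA, configB, loci, seed_pair)
        _, _, shared = shared_deserts_for_pair(callsA, callsB, rmap)
        if len(shared):
            on_locus = (
                (shared["chrom"] == chrom)
                & (shared["start_bp"] <= pos)
                & (pos < shared["end_bp"])
            )
            hits += int(on_locus.any())
    return {"power": hits / n_replicates, "hits": hits, "n_replicates": n_replicates, "s": s}


def neutral_shared_deserts(
    n_replicates: int = 30,
    seed: Optional[int] = None,
    N_hybrid: int = 1000,
) -> dict:
    """Genome-wide count of shared deserts between fully neutral replicate
    pairs (the pipeline's false-positive background)."""
    configA, configB = paired_population_configs(N_hybrid)
    rmap = configA.recomb_map
    counts = []
    for seed_pair in _pair_seeds(seed, n_replicates):
        callsA, callsB = _run_pair(configA, configB, [], seed_pair)
        _, _, shared = shared_deserts_for_pair(callsA, callsB, rmap)
        counts.append(len(shared))
    counts = np.asarray(counts)
    return {
        "mean_shared": float(counts.mean()),
        "counts": counts,
        "n_replicates": n_replicates,
    }
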