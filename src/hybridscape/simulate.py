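"""Forward-in-time diploid Wright-Fisher admixture simulator.

Simulates a hybrid population formed from two parental species, tracking
local ancestry as explicit tract lists per haplotype.  Each generation:
fitness assignment under a configurable selection model, Wright-Fisher
sampling of parents proportional to fitness, meiosis with a Poisson number
of crossovers placed along the genetic map (no interference), and migration
that replaces individuals with pure parental genotypes.

Coordinates: tracts are 0-based half-open ``[start_bp, end_bp)``; marker
positions elsewhere in the package are 1-based.  Haplotypes are stored as
(segment-end, source) array pairs; with no crossover a gamete shares its
parent's arrays, which keeps neutral generations cheap.

Selection models
----------------
``directional``
    Additive selection against minor-parent ancestry at each selected locus:
    relative fitness 1, 1-s/2, 1-s for minor dosage 0, 1, 2.
``dmi_pairs``
    Two-locus Dobzhansky-Muller incompatibility: alleles derived from
    *different* parents at the two partner loci are incompatible.  With
    dosages d1 (parent-1 ancestry at locus 1) and d2 (parent-2 ancestry at
    locus 2), the number of incompatible pairings is d1*d2 (0..4) and
    fitness is multiplied by ``1 - s * (d1*d2/4)**dmi_dominance``
    (codominant by default, ``dmi_dominance=1``).
``mitonuclear``
    Penalty for minor-parent nuclear ancestry at the locus on the mismatched
    (major-parent) mitochondrial background: 1, 1-s/2, 1-s by minor dosage,
    applied only when the individual's mitochondrion is major-parent.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .callset import MISSING, AncestryCallSet
from .maps import RecombMap

__all__ = [
    "SimConfig",
    "SimPopulation",
    "simulate_hybrid_population",
    "tracts_to_calls",
    "inject_call_errors",
    "simulate_replicate_pair",
    "summarize_tracts",
    "mean_ancestry",
]

PARENT1, PARENT2 = 0, 1


@dataclass
class SimConfig:
    """Parameters of one hybrid-population simulation.

    ``selected_loci`` entries depend on the model: ``(chrom, pos, s)`` for
    directional and mitonuclear; ``((chrom1, pos1), (chrom2, pos2), s)`` for
    dmi_pairs.  An entry with ``s=None`` draws s from an exponential
    distribution with mean ``s_mean`` at simulation start.
    """

    n_chromosomes: int = 5
    chrom_length_bp: int = 25_000_000
    recomb_map: Optional[RecombMap] = None
    recomb_rate_morgans_per_bp: float = 1e-8  # used when recomb_map is None
    N_hybrid: int = 1000
    p0: float = 0.76  # initial proportion of ancestry from parent 1 (major)
    t_admix: int = 100
    m1: float = 0.0  # per-generation migration rate from parent 1
    m2: float = 0.0
    selection_model: str = "neutral"
    selected_loci: list = field(default_factory=list)
    s_mean: Optional[float] = None
    dmi_dominance: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.5 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0.5, 1]")
        if self.N_hybrid < 2:
            raise ValueError("N_hybrid must be >= 2")
        if self.t_admix < 1:
            raise ValueError("t_admix must be >= 1")
        # migration rates are per-generation replacement probabilities; the
        # demographic prior tops out at 0.03 but the simulator accepts any
        # probability (m=1 models complete replacement)
        if not (0.0 <= self.m1 <= 1.0 and 0.0 <= self.m2 <= 1.0 and self.m1 + self.m2 <= 1.0):
            raise ValueError("migration rates must be probabilities with m1+m2 <= 1")
        if self.selection_model not in ("neutral", "directional", "dmi_pairs", "mitonuclear"):
            raise ValueError(f"unknown selection model {self.selection_model!r}")
        if self.recomb_map is None:
            lengths = {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}
            rate = self.recomb_rate_morgans_per_bp * 100 * 1e6  # cM/Mb
            self.recomb_map = RecombMap.uniform(lengths, rate)
        self._check_loci()

    def _check_loci(self) -> None:
        for locus in self.selected_loci:
            pts = locus[:2] if self.selection_model == "dmi_pairs" else [locus[:2]]
            for chrom, pos in pts:
                if chrom not in self.recomb_map.chroms:
                    raise ValueError(f"selected locus on unknown chromosome {chrom!r}")
                if not 0 <= pos < self.recomb_map.chrom_length(chrom):
                    raise ValueError(f"selected locus {chrom}:{pos} off chromosome")

    @property
    def chroms(self) -> list[str]:
        return self.recomb_map.chroms


@dataclass
class SimPopulation:
    """Evolved hybrid population: ancestry tracts per haplotype.

    ``haplotypes[chrom]`` is a list of 2N (breaks, sources) pairs; haplotypes
    2i and 2i+1 belong to diploid individual i.  ``breaks`` is an ascending
    Python list of segment end positions (bp, last equals the chromosome
    length) and ``sources`` the tract source (0 = parent 1, 1 = parent 2);
    plain lists keep the per-meiosis splice cheap.
    """

    config: SimConfig
    haplotypes: dict[str, list]
    mito: np.ndarray  # (N,) int8 source of the mitochondrion
    generation: int
    ancestry_extinct: Optional[int] = None  # source lost genome-wide, if any

    @property
    def n_individuals(self) -> int:
        return self.mito.shape[0]

    def tracts(self, chrom: str, hap_index: int) -> list[tuple[int, int, int]]:
        """Tract list ``(start_bp, end_bp, source)`` for one haplotype."""
        breaks, src = self.haplotypes[chrom][hap_index]
        starts = [0.0] + list(breaks[:-1])
        return [(int(a), int(b), int(s)) for a, b, s in zip(starts, breaks, src)]


# ---------------------------------------------------------------------------
# meiosis

def _splice(hapA, hapB, xs, first: int):
    """Recombine two haplotypes at sorted crossover positions ``xs``."""
    haps = (hapA, hapB)
    cur = first
    prev = 0.0
    ob: list[float] = []
    osrc: list[int] = []
    for x in xs:
        b, s = haps[cur]
        i = bisect_right(b, prev)
        j = bisect_left(b, x)
        ob.extend(b[i:j])
        osrc.extend(s[i:j])
        ob.append(x)
        osrc.append(s[j] if j < len(s) else s[-1])
        prev = x
        cur ^= 1
    b, s = haps[cur]
    i = bisect_right(b, prev)
    ob.extend(b[i:])
    osrc.extend(s[i:])
    # merge adjacent same-source segments (zero-length cuts are measure-zero
    # for continuous crossover positions and need no special handling)
    nb: list[float] = []
    ns: list[int] = []
    for bk, sk in zip(ob, osrc):
        if ns and ns[-1] == sk:
            nb[-1] = bk
        else:
            nb.append(bk)
            ns.append(sk)
    return nb, ns


def _source_at(hap, pos: float) -> int:
    breaks, src = hap
    return src[bisect_right(breaks, pos)]


def _pure_hap(length: float, source: int):
    return ([length], [source])


# ---------------------------------------------------------------------------
# fitness

def _dosage(haps_c: list, i: int, pos: float, source: int) -> int:
    """Ancestry dosage of ``source`` for individual i at (chrom-local) pos."""
    return int(_source_at(haps_c[2 * i], pos) == source) + int(
        _source_at(haps_c[2 * i + 1], pos) == source
    )


def _fitness(config: SimConfig, haps: dict, mito: np.ndarray, loci) -> np.ndarray:
    N = mito.shape[0]
    w = np.ones(N)
    model = config.selection_model
    if model == "neutral" or not loci:
        return w
    if model == "directional":
        for chrom, pos, s in loci:
            hc = haps[chrom]
            for i in range(N):
                d = _dosage(hc, i, pos, PARENT2)
                if d:
                    w[i] *= 1.0 - s * d / 2.0
    elif model == "dmi_pairs":
        h = config.dmi_dominance
        for (c1, p1), (c2, p2), s in loci:
            h1, h2 = haps[c1], haps[c2]
            for i in range(N):
                d1 = _dosage(h1, i, p1, PARENT1)
                d2 = _dosage(h2, i, p2, PARENT2)
                k = d1 * d2
                if k:
                    w[i] *= 1.0 - s * (k / 4.0) ** h
    elif model == "mitonuclear":
        for chrom, pos, s in loci:
            hc = haps[chrom]
            for i in range(N):
                if mito[i] == PARENT1:  # mismatched (major-parent) background
                    d = _dosage(hc, i, pos, PARENT2)
                    if d:
                        w[i] *= 1.0 - s * d / 2.0
    return np.maximum(w, 0.0)


# ---------------------------------------------------------------------------
# main loop

def simulate_hybrid_population(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimPopulation:
    """Evolve a hybrid population for ``config.t_admix`` generations.

    Returns the final :class:`SimPopulation`.  If one ancestry is lost
    genome-wide the simulation completes and the loss is reported on
    ``ancestry_extinct`` rather than raising.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = config.N_hybrid
    rmap = config.recomb_map
    chroms = config.chroms
    lengths = {c: float(rmap.chrom_length(c)) for c in chroms}
    map_len_morgans = {c: rmap.chrom_length_cm(c) / 100.0 for c in chroms}
    if any(L <= 0 for L in lengths.values()):
        raise ValueError("zero-length chromosome")

    # resolve selection coefficients drawn from the exponential regime
    loci = []
    for locus in config.selected_loci:
        *where, s = locus
        if s is None:
            if config.s_mean is None:
                raise ValueError("locus with s=None requires s_mean")
            s = float(rng.exponential(config.s_mean))
        loci.append((*where, min(s, 1.0)))

    # founders: pure parental diploids, parent 1 with probability p0
    founder_src = (rng.random(N) >= config.p0).astype(np.int8)  # 1 = parent2
    haps = {
        c: [_pure_hap(lengths[c], int(founder_src[i // 2])) for i in range(2 * N)]
        for c in chroms
    }
    mito = founder_src.copy()

    pure = {c: (_pure_hap(lengths[c], PARENT1), _pure_hap(lengths[c], PARENT2)) for c in chroms}
    m_tot = config.m1 + config.m2

    for gen in range(config.t_admix):
        # the founding generation mates at random: hybridization happens
        # first, selection acts on hybrid genotypes from the F1s onward
        # (otherwise strong selection culls pure-minor founders before any
        # admixed genotype can form)
        if gen == 0:
            w = np.ones(N)
        else:
            w = _fitness(config, haps, mito, loci)
        tot = w.sum()
        if tot <= 0:  # all individuals inviable: resample uniformly
            p = np.full(N, 1.0 / N)
        else:
            p = w / tot
        parents = rng.choice(N, size=(N, 2), p=p)
        start_hap = rng.integers(0, 2, size=(N, 2, len(chroms)), dtype=np.int8)
        new_haps = {}
        for ci, c in enumerate(chroms):
            hc = haps[c]
            L = lengths[c]
            n_x = rng.poisson(map_len_morgans[c], size=(N, 2))
            total_x = int(n_x.sum())
            if total_x:
                # crossover positions drawn uniformly on the genetic map
                xs_cm = rmap.cum_cm[c][0] + rng.random(total_x) * rmap.chrom_length_cm(c)
                xs_bp = rmap.gen_to_phys(c, xs_cm).tolist()
            else:
                xs_bp = []
            out = [None] * (2 * N)
            ofs = 0
            nx_flat = n_x.ravel().tolist()
            start_flat = start_hap[:, :, ci].ravel().tolist()
            par_list = parents.ravel().tolist()
            for g in range(2 * N):
                par = par_list[g]
                k = nx_flat[g]
                first = start_flat[g]
                if k == 0:
                    out[g] = hc[2 * par + first]
                else:
                    xs = sorted(xs_bp[ofs : ofs + k])
                    ofs += k
                    out[g] = _splice(hc[2 * par + first], hc[2 * par + 1 - first], xs, 0)
            new_haps[c] = out
        mito = mito[parents[:, 0]]
        haps = new_haps
        # migration: replace whole individuals with pure parental migrants
        if m_tot > 0:
            u = rng.random(N)
            migrants = np.nonzero(u < m_tot)[0]
            for i in migrants:
                src = PARENT1 if u[i] < config.m1 else PARENT2
                for c in chroms:
                    haps[c][2 * i] = pure[c][src]
                    haps[c][2 * i + 1] = pure[c][src]
                mito[i] = src

    pop = SimPopulation(config, haps, mito, config.t_admix)
    for source in (PARENT1, PARENT2):
        if mean_ancestry(pop, source) == 0.0:
            pop.ancestry_extinct = source
    return pop


# ---------------------------------------------------------------------------
# derived quantities

def mean_ancestry(pop: SimPopulation, source: int = PARENT2) -> float:
    """Genome-wide mean proportion of ``source`` ancestry (tract-integrated)."""
    total = 0.0
    covered = 0.0
    for c in pop.config.chroms:
        for breaks, src in pop.haplotypes[c]:
            prev = 0.0
            covered += breaks[-1]
            for b, s in zip(breaks, src):
                if s == source:
                    total += b - prev
                prev = b
    return float(total / covered)


def count_junctions(pop: SimPopulation) -> float:
    """Mean number of ancestry junctions per haplotype, genome-wide."""
    n = 0
    for c in pop.config.chroms:
        for breaks, _src in pop.haplotypes[c]:
            n += len(breaks) - 1
    return n / (2 * pop.n_individuals)


def summarize_tracts(pop: SimPopulation, source: int) -> dict:
    """Median and full distribution of tract lengths (bp) for ``source``.

    Raises ``ValueError`` when the requested ancestry is absent genome-wide.
    """
    lens = []
    for c in pop.config.chroms:
        for breaks, src in pop.haplotypes[c]:
            prev = 0.0
            for b, s in zip(breaks, src):
                if s == source:
                    lens.append(b - prev)
                prev = b
    lens = np.asarray(lens, dtype=float)
    if lens.size == 0:
        raise ValueError(f"ancestry source {source} absent genome-wide")
    return {"median_bp": float(np.median(lens)), "lengths_bp": lens}


def tracts_to_calls(
    pop: SimPopulation,
    sites: dict[str, np.ndarray],
    minor_parent: Optional[int] = None,
    individuals: Optional[Sequence[int]] = None,
) -> AncestryCallSet:
    """Project tract ancestry onto 1-based marker positions.

    The dosage at a site is the number of haplotypes whose covering tract
    (half-open, 0-based) is minor-parent; posteriors are 1.0 on the true
    state.  ``minor_parent`` defaults to the source with the lower
    genome-wide mean ancestry in ``pop``.
    """
    if minor_parent is None:
        minor_parent = PARENT2 if mean_ancestry(pop, PARENT2) <= 0.5 else PARENT1
    if individuals is None:
        individuals = range(pop.n_individuals)
    individuals = list(individuals)
    chrom_arr, pos_arr = [], []
    for c in pop.config.chroms:
        if c not in sites:
            continue
        s = np.asarray(sites[c], dtype=np.int64)
        if s.size and (s.min() < 1 or s.max() > pop.config.recomb_map.chrom_length(c)):
            raise ValueError(f"site outside chromosome {c}")
        chrom_arr.append(np.full(s.size, c, dtype=object))
        pos_arr.append(s)
    chrom_arr = np.concatenate(chrom_arr)
    pos_arr = np.concatenate(pos_arr)
    n_sites = pos_arr.size
    state = np.zeros((len(individuals), n_sites), dtype=np.int8)  # copies of parent2
    col = 0
    for c in pop.config.chroms:
        if c not in sites:
            continue
        s = np.asarray(sites[c], dtype=np.float64) - 1.0  # 1-based -> 0-based bp
        hc = pop.haplotypes[c]
        for row, i in enumerate(individuals):
            for hap in (hc[2 * i], hc[2 * i + 1]):
                breaks = np.asarray(hap[0])
                src = np.asarray(hap[1], dtype=np.int8)
                idx = np.searchsorted(breaks, s, side="right")
                state[row, col : col + s.size] += src[np.minimum(idx, len(src) - 1)]
        col += s.size
    post = np.zeros((len(individuals), n_sites, 3))
    for k in range(3):
        post[:, :, k] = state == k
    cs = AncestryCallSet(chrom_arr, pos_arr, post, np.zeros_like(state), minor_parent)
    cs.hard_calls = cs.state_to_minor_dosage(state)
    return cs


def inject_call_errors(calls: AncestryCallSet, error_rate: float, seed=None) -> AncestryCallSet:
    """Independently corrupt each non-missing hard call with probability
    ``error_rate``, replacing it with a uniformly chosen *different* state;
    posteriors are reset to 1.0 on the new state."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hard = calls.hard_calls.copy()
    post = calls.posteriors.copy()
    ok = hard >= 0
    flip = ok & (rng.random(hard.shape) < error_rate)
    if flip.any():
        old = hard[flip]
        shift = rng.integers(1, 3, size=old.size)  # +1 or +2 mod 3 -> different
        new = ((old + shift) % 3).astype(np.int8)
        hard[flip] = new
        # rebuild posteriors at flipped entries (state = copies of parent2)
        state = new if calls.minor_parent == 1 else 2 - new
        rows, cols = np.nonzero(flip)
        post[rows, cols, :] = 0.0
        post[rows, cols, state] = 1.0
    return AncestryCallSet(calls.chrom, calls.pos, post, hard, calls.minor_parent, list(calls.individuals))


def simulate_replicate_pair(
    configA: SimConfig,
    configB: SimConfig,
    shared_selected_loci: list,
    seedA: int,
    seedB: int,
    sites: Optional[dict[str, np.ndarray]] = None,
    site_spacing_bp: int = 10_000,
    n_sample_A: Optional[int] = None,
    n_sample_B: Optional[int] = None,
) -> tuple[AncestryCallSet, AncestryCallSet]:
    """Two independent hybrid populations sharing only the selection
    architecture (and the recombination map); returns sampled call sets."""
    if seedA == seedB:
        raise ValueError("replicate seeds must differ")
    if configA.chroms != configB.chroms or any(
        configA.recomb_map.chrom_length(c) != configB.recomb_map.chrom_length(c)
        for c in configA.chroms
    ):
        raise ValueError("replicate configs must share chromosome structure")
    if sites is None:
        sites = {
            c: np.arange(site_spacing_bp, configA.recomb_map.chrom_length(c) + 1, site_spacing_bp)
            for c in configA.chroms
        }
    out = []
    for config, seed, n_sample in ((configA, seedA, n_sample_A), (configB, seedB, n_sample_B)):
        cfg = SimConfig(**{**config.__dict__, "selected_loci": list(shared_selected_loci), "seed": seed})
        rng = np.random.default_rng(seed)
        pop = simulate_hybrid_population(cfg, rng)
        inds = None
        if n_sample is not None and n_sample < pop.n_individuals:
            inds = rng.choice(pop.n_individuals, size=n_sample, replace=False)
        out.append(tracts_to_calls(pop, sites, minor_parent=PARENT2, individuals=inds))
    return out[0], out[1]
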