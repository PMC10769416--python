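"""Forward-simulator behavior: ancestry conservation, selection limits,
junction accumulation, tract bookkeeping, and call projection."""

import numpy as np
import pytest

from hybridscape import SimConfig, simulate_hybrid_population, simulate_replicate_pair, tracts_to_calls
from hybridscape.simulate import (
    PARENT1,
    PARENT2,
    count_junctions,
    inject_call_errors,
    mean_ancestry,
    summarize_tracts,
)


def _cfg(**kw):
    base = dict(n_chromosomes=1, chrom_length_bp=20_000_000, N_hybrid=200, p0=0.76, t_admix=20)
    base.update(kw)
    return SimConfig(**base)


class TestNeutralDynamics:
    def test_neutral_mean_ancestry_near_p0(self):
        """Neutral drift preserves the expected admixture proportion."""
        vals = [
            mean_ancestry(simulate_hybrid_population(_cfg(N_hybrid=1000, t_admix=50, seed=s)), PARENT2)
            for s in range(5)
        ]
        # founder binomial sd ~ 0.0095 at N=1000 plus drift: generous 4-sigma band
        assert abs(np.mean(vals) - 0.24) < 0.04

    @pytest.mark.parametrize("N", [50, 500, 5000])
    def test_law_of_large_numbers(self, N):
        """|mean ancestry - p0| shrinks as N grows."""
        dev = [
            abs(mean_ancestry(simulate_hybrid_population(_cfg(N_hybrid=N, t_admix=5, seed=s)), PARENT2) - 0.24)
            for s in range(4)
        ]
        # store for cross-parameter comparison via cache on the class
        TestNeutralDynamics._lln = getattr(TestNeutralDynamics, "_lln", {})
        TestNeutralDynamics._lln[N] = np.mean(dev)
        if len(TestNeutralDynamics._lln) == 3:
            d = TestNeutralDynamics._lln
            assert d[5000] < d[50]

    def test_junction_density_matches_wf_oracle(self):
        """Mean junctions per Morgan agree with an independent marker-matrix
        Wright-Fisher Monte Carlo under identical founding conditions."""
        N, t, p = 80, 12, 0.5
        reps = 12

        def oracle(seed):
            # marker-resolution WF simulation: 256 loci over 1 Morgan
            rng = np.random.default_rng(seed)
            M = 256
            gpos = np.linspace(0, 1, M, endpoint=False)
            founders = (rng.random(N) >= p).astype(np.int8)
            hap = np.repeat(founders, 2)[:, None] * np.ones(M, dtype=np.int8)
            for _ in range(t):
                parents = rng.choice(N, size=(N, 2))
                new = np.empty_like(hap)
                for i in range(N):
                    for g in range(2):
                        par = parents[i, g]
                        k = rng.poisson(1.0)
                        xs = np.sort(rng.random(k))
                        phase = (np.searchsorted(xs, gpos, side="right") + rng.integers(2)) % 2
                        h0, h1 = hap[2 * par], hap[2 * par + 1]
                        new[2 * i + g] = np.where(phase == 0, h0, h1)
                hap = new
            return np.abs(np.diff(hap.astype(int), axis=1)).sum() / (2 * N)

        exp = np.mean([oracle(100 + r) for r in range(reps)])
        obs = []
        for r in range(reps):
            cfg = SimConfig(
                n_chromosomes=1,
                chrom_length_bp=10_000_000,
                recomb_rate_morgans_per_bp=1e-7,
                N_hybrid=N,
                p0=p,
                t_admix=t,
                seed=200 + r,
            )
            obs.append(count_junctions(simulate_hybrid_population(cfg)))
        assert np.mean(obs) == pytest.approx(exp, rel=0.12)

    def test_junction_density_large_n_formula(self):
        """At large N the junction density approaches 2*p0*(1-p0)*t per
        Morgan (one founding generation produces no junctions)."""
        p, t = 0.5, 25
        cfg = SimConfig(
            n_chromosomes=1,
            chrom_length_bp=20_000_000,
            recomb_rate_morgans_per_bp=5e-8,
            N_hybrid=3000,
            p0=p,
            t_admix=t,
            seed=7,
        )
        per_morgan = count_junctions(simulate_hybrid_population(cfg)) / 1.0
        assert per_morgan == pytest.approx(2 * p * (1 - p) * t, rel=0.10)


class TestSelection:
    def test_lethal_directional_selection_removes_minor_allele(self):
        cfg = _cfg(
            N_hybrid=500,
            t_admix=20,
            selection_model="directional",
            selected_loci=[("chr1", 10_000_000, 1.0)],
            seed=3,
        )
        pop = simulate_hybrid_population(cfg)
        calls = tracts_to_calls(pop, {"chr1": np.array([10_000_000])}, minor_parent=PARENT2)
        assert (calls.hard_calls == 0).all()

    def test_selection_monotonic_in_s(self):
        """Mean minor ancestry at the selected locus is non-increasing in s."""
        freqs = []
        for s in [0.0, 0.05, 0.25]:
            vals = []
            for seed in range(3):
                cfg = _cfg(
                    N_hybrid=400,
                    t_admix=40,
                    selection_model="directional" if s else "neutral",
                    selected_loci=[("chr1", 10_000_000, s)] if s else [],
                    seed=seed,
                )
                pop = simulate_hybrid_population(cfg)
                c = tracts_to_calls(pop, {"chr1": np.array([10_000_000])}, minor_parent=PARENT2)
                vals.append(c.site_mean_minor()[0])
            freqs.append(np.mean(vals))
        assert freqs[0] >= freqs[1] >= freqs[2]

    def test_dmi_and_mitonuclear_reduce_target_ancestry(self):
        base = dict(n_chromosomes=2, chrom_length_bp=20_000_000, N_hybrid=300, p0=0.76, t_admix=30)
        neutral = simulate_hybrid_population(SimConfig(**base, seed=11))
        dmi = simulate_hybrid_population(
            SimConfig(
                **base,
                selection_model="dmi_pairs",
                selected_loci=[(("chr1", 5_000_000), ("chr2", 5_000_000), 0.8)],
                seed=11,
            )
        )
        mito = simulate_hybrid_population(
            SimConfig(
                **base,
                selection_model="mitonuclear",
                selected_loci=[("chr1", 5_000_000, 0.9)],
                seed=11,
            )
        )
        site = {"chr1": np.array([5_000_000])}
        f_neutral = tracts_to_calls(neutral, site, PARENT2).site_mean_minor()[0]
        f_mito = tracts_to_calls(mito, site, PARENT2).site_mean_minor()[0]
        assert f_mito < f_neutral
        # DMI removes one of the two incompatible combinations
        f_dmi2 = tracts_to_calls(dmi, {"chr2": np.array([5_000_000])}, PARENT2).site_mean_minor()[0]
        f_neu2 = tracts_to_calls(neutral, {"chr2": np.array([5_000_000])}, PARENT2).site_mean_minor()[0]
        assert f_dmi2 < f_neu2


class TestLifecycle:
    def test_total_migration_replaces_population(self):
        cfg = _cfg(N_hybrid=50, t_admix=1, m1=1.0, m2=0.0, seed=5)
        pop = simulate_hybrid_population(cfg)
        assert mean_ancestry(pop, PARENT1) == 1.0
        assert pop.ancestry_extinct == PARENT2

    def test_tract_tiling_invariant(self, small_pop):
        """Tracts per haplotype are sorted, tile [0, L), and alternate."""
        for c in small_pop.config.chroms:
            L = small_pop.config.recomb_map.chrom_length(c)
            for h in range(2 * small_pop.n_individuals):
                tr = small_pop.tracts(c, h)
                assert tr[0][0] == 0 and tr[-1][1] == L
                for (a, b, s), (a2, b2, s2) in zip(tr, tr[1:]):
                    assert b == a2 and a < b and s != s2

    def test_selected_locus_off_chromosome_rejected(self):
        with pytest.raises(ValueError, match="off chromosome|unknown"):
            _cfg(selection_model="directional", selected_loci=[("chr1", 10**9, 0.1)])


class TestTractSummaries:
    def test_generation_zero_tracts_span_chromosomes(self):
        cfg = _cfg(N_hybrid=100, t_admix=1, recomb_rate_morgans_per_bp=0.0, seed=2)
        pop = simulate_hybrid_population(cfg)
        res = summarize_tracts(pop, PARENT2)
        assert (res["lengths_bp"] == 20_000_000).all()

    def test_median_tract_length_decreases_with_time(self):
        meds = []
        for t in (5, 40, 120):
            pop = simulate_hybrid_population(_cfg(N_hybrid=300, t_admix=t, seed=9))
            meds.append(summarize_tracts(pop, PARENT2)["median_bp"])
        assert meds[0] > meds[1] > meds[2]

    def test_absent_source_raises(self):
        cfg = _cfg(N_hybrid=50, t_admix=1, p0=1.0, seed=1)
        pop = simulate_hybrid_population(cfg)
        with pytest.raises(ValueError, match="absent"):
            summarize_tracts(pop, PARENT2)


class TestCallProjection:
    def test_dosage_matches_tract_integration(self, small_pop, small_calls):
        """Mean dosage/2 over dense markers equals tract-integrated ancestry
        up to marker discretization."""
        direct = mean_ancestry(small_pop, PARENT2)
        marker = np.nanmean(small_calls.site_mean_minor())
        assert marker == pytest.approx(direct, abs=0.003)

    def test_boundary_site_belongs_to_covering_tract(self):
        cfg = _cfg(N_hybrid=2, t_admix=1, seed=0)
        pop = simulate_hybrid_population(cfg)
        # construct a haplotype pair with a known breakpoint at 1,000,000
        pop.haplotypes["chr1"] = [
            ([1_000_000.0, 20_000_000.0], [0, 1]),
            ([1_000_000.0, 20_000_000.0], [0, 1]),
            ([20_000_000.0], [1]),
            ([20_000_000.0], [1]),
        ]
        # site 1,000,001 (1-based) occupies 0-based bp 1,000,000 -> second tract
        calls = tracts_to_calls(pop, {"chr1": np.array([1_000_000, 1_000_001])}, PARENT2)
        assert calls.hard_calls[0, 0] == 0 and calls.hard_calls[0, 1] == 2
        assert tuple(calls.posteriors[0, 1]) == (0.0, 0.0, 1.0)

    def test_posteriors_are_degenerate_on_truth(self, small_calls):
        assert np.allclose(small_calls.posteriors.sum(axis=2), 1.0)
        assert set(np.unique(small_calls.posteriors)) <= {0.0, 1.0}


class TestErrorInjection:
    def test_zero_and_full_error_rates(self, small_calls):
        same = inject_call_errors(small_calls, 0.0, seed=1)
        assert np.array_equal(same.hard_calls, small_calls.hard_calls)
        flipped = inject_call_errors(small_calls, 1.0, seed=1)
        ok = small_calls.hard_calls >= 0
        assert (flipped.hard_calls[ok] != small_calls.hard_calls[ok]).all()

    def test_error_fraction_binomial(self, small_calls):
        noisy = inject_call_errors(small_calls, 0.05, seed=2)
        ok = small_calls.hard_calls >= 0
        frac = (noisy.hard_calls[ok] != small_calls.hard_calls[ok]).mean()
        n = ok.sum()
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n)

    def test_posteriors_follow_flips(self, small_calls):
        noisy = inject_call_errors(small_calls, 0.5, seed=3)
        state = noisy.hard_calls.copy()  # minor_parent=1: state == dosage
        ok = state >= 0
        rows, cols = np.nonzero(ok)
        assert np.allclose(
            noisy.posteriors[rows, cols, state[ok]], 1.0
        )


class TestReplicatePairs:
    def test_identical_seeds_refused(self):
        a = _cfg(seed=None)
        with pytest.raises(ValueError, match="seeds"):
            simulate_replicate_pair(a, a, [], seedA=5, seedB=5)

    def test_neutral_pairs_uncorrelated_and_shared_selection_correlated(self):
        """Window ancestry in independent neutral replicates is uncorrelated;
        strong shared selection (s ~ Exp(0.5)) induces a positive cross-
        population correlation."""
        from hybridscape.corr import cross_population_correlation
        from hybridscape.io import make_windows, window_summary
        from hybridscape.maps import RecombMap

        rmap = RecombMap.uniform({f"chr{i + 1}": 25_000_000 for i in range(5)}, 1.0)
        # strong genome-wide selection purges minor ancestry on a small
        # genome if it runs for long; a short post-hybridization horizon at
        # larger N keeps the shared purge pattern and segregating ancestry
        base = dict(
            n_chromosomes=5, chrom_length_bp=25_000_000, recomb_map=rmap,
            N_hybrid=2000, p0=0.76, t_admix=25,
        )
        frame = make_windows(rmap, "physical", 100_000)

        def rho(loci, model, seeds):
            ca, cb = simulate_replicate_pair(
                SimConfig(**base, selection_model=model),
                SimConfig(**base, selection_model=model),
                loci, *seeds, site_spacing_bp=10_000, n_sample_A=100, n_sample_B=100,
            )
            ta = window_summary(ca, frame)
            tb = window_summary(cb, frame)
            return cross_population_correlation(ta, tb, spacing_bp=1_000_000).rho

        rng = np.random.default_rng(99)
        loci = [(f"chr{i + 1}", int(p), float(rng.exponential(0.5)))
                for i in range(3) for p in (6_250_000, 18_750_000)]
        neutral = np.mean([rho([], "neutral", (11, 12)), rho([], "neutral", (13, 14))])
        selected = np.mean([rho(loci, "directional", s)
                            for s in ((15, 16), (17, 18), (19, 20))])
        assert abs(neutral) < 0.25
        assert selected > 0.4
        assert selected > neutral + 0.3
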