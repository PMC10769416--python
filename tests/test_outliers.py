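"""Desert/island detection, merging, sharing, permutation nulls and time
trends."""

import numpy as np
import pandas as pd
import pytest

from hybridscape.maps import RecombMap
from hybridscape.outliers import (
    PopulationWindows,
    _detect_runs,
    detect_outlier_regions,
    genome_quantiles,
    merge_and_filter,
    permutation_null_naive,
    permutation_null_shift,
    shared_regions,
    timeseries_trend,
    timeseries_trends,
)


class TestGenomeQuantiles:
    def test_uniform_values(self):
        rng = np.random.default_rng(0)
        q = genome_quantiles(rng.random(20_000), rng.random(20_000))
        assert q["q05_site"] == pytest.approx(0.05, abs=0.01)
        assert q["q90_window"] == pytest.approx(0.90, abs=0.01)

    def test_site_just_above_quantile_is_not_a_seed(self):
        """A site at 2.3% minor ancestry with a 2.2% genome-wide 5% quantile
        does not seed a desert."""
        q = {"q05_site": 0.022, "q10_window": 0.05, "q95_site": 1.0, "q90_window": 1.0}
        w = _toy_population(
            window_means=[0.2, 0.02, 0.2], min_sites=[0.2, 0.023, 0.2], quantiles=q
        )
        assert len(_detect_runs(w, "desert")) == 0

    def test_degenerate_distribution(self):
        q = genome_quantiles(np.full(200, 0.3), np.full(200, 0.3))
        assert q["q05_site"] == q["q95_site"] == 0.3

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="100"):
            genome_quantiles(np.random.random(10), np.random.random(500))


def _toy_population(window_means, min_sites=None, max_sites=None, quantiles=None,
                    window_bp=50_000, n_sites=5, n_map=5, chrom="chr1"):
    n = len(window_means)
    means = np.asarray(window_means, dtype=float)
    starts = np.arange(n) * window_bp
    w = pd.DataFrame(
        {
            "chrom": chrom,
            "start_bp": starts,
            "end_bp": starts + window_bp,
            "gstart_cM": starts / 1e6,
            "gend_cM": (starts + window_bp) / 1e6,
            "mean_minor_ancestry": means,
            "min_site": means if min_sites is None else np.asarray(min_sites, float),
            "max_site": means if max_sites is None else np.asarray(max_sites, float),
            "n_sites": n_sites,
            "n_calls": n_sites * 50,
            "n_map_snps": n_map,
        }
    )
    if quantiles is None:
        quantiles = {
            "q05_site": np.quantile(means, 0.05),
            "q10_window": np.quantile(means, 0.10),
            "q95_site": np.quantile(means, 0.95),
            "q90_window": np.quantile(means, 0.90),
        }
    return PopulationWindows(w, quantiles)


def brute_force_desert_scan(pw, kind="desert"):
    """Oracle: for every seed site, expand window-by-window in both
    directions while windows stay within the tail; collect distinct
    regions."""
    w = pw.windows
    q = pw.quantiles
    mean = w["mean_minor_ancestry"].to_numpy()
    if kind == "desert":
        tail = (mean <= q["q10_window"]) & np.isfinite(mean)
        seed = (w["min_site"].to_numpy() <= q["q05_site"]) & tail
    else:
        tail = (mean >= q["q90_window"]) & np.isfinite(mean)
        seed = (w["max_site"].to_numpy() >= q["q95_site"]) & tail
    chrom = w["chrom"].to_numpy()
    out = set()
    for i in np.nonzero(seed)[0]:
        lo = i
        while lo - 1 >= 0 and tail[lo - 1] and chrom[lo - 1] == chrom[i]:
            lo -= 1
        hi = i
        while hi + 1 < len(w) and tail[hi + 1] and chrom[hi + 1] == chrom[i]:
            hi += 1
        out.add((chrom[i], int(w["start_bp"].iloc[lo]), int(w["end_bp"].iloc[hi])))
    return sorted(out)


class TestDetection:
    def test_toy_expansion_matches_hand_scan(self):
        """Windows [.30,.30,.04,.02,.05,.30] with a seed in the middle give
        one region spanning the three tail windows."""
        q = {"q05_site": 0.02, "q10_window": 0.08, "q95_site": 1.1, "q90_window": 1.1}
        pw = _toy_population([0.30, 0.30, 0.04, 0.02, 0.05, 0.30], quantiles=q)
        regions = _detect_runs(pw, "desert")
        assert len(regions) == 1
        assert regions["start_bp"].iloc[0] == 2 * 50_000
        assert regions["end_bp"].iloc[0] == 5 * 50_000

    def test_no_regions_when_all_equal(self):
        pw = _toy_population(np.full(40, 0.2))
        # all windows tie at the quantile: seeds everywhere -> whole genome
        # would qualify; use strict construction with no sites in the tail
        pw.quantiles = {"q05_site": 0.1, "q10_window": 0.1, "q95_site": 0.3, "q90_window": 0.3}
        assert len(_detect_runs(pw, "desert")) == 0

    def test_seed_window_above_window_tail_rejected(self):
        q = {"q05_site": 0.02, "q10_window": 0.05, "q95_site": 1.1, "q90_window": 1.1}
        # min site in the tail but its window mean (0.2) above the 10% tail
        pw = _toy_population([0.3, 0.2, 0.3], min_sites=[0.3, 0.01, 0.3], quantiles=q)
        assert len(_detect_runs(pw, "desert")) == 0

    @pytest.mark.parametrize("kind", ["desert", "island"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_random_windows(self, kind, seed):
        rng = np.random.default_rng(seed)
        n = 200
        means = rng.beta(2, 6, size=n)
        mins = means * rng.random(n)
        maxs = means + (1 - means) * rng.random(n)
        pw = _toy_population(means, min_sites=mins, max_sites=maxs)
        got = _detect_runs(pw, kind)
        got_set = sorted(
            (r["chrom"], int(r["start_bp"]), int(r["end_bp"])) for _, r in got.iterrows()
        )
        assert got_set == brute_force_desert_scan(pw, kind)

    def test_detection_idempotent(self, small_calls, small_map):
        a = detect_outlier_regions(small_calls, small_map, "desert")
        b = detect_outlier_regions(small_calls, small_map, "desert")
        pd.testing.assert_frame_equal(a, b)


class TestMergeFilter:
    def _regions(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start_bp", "end_bp", "kind", "mean_minor_ancestry",
                "n_aims", "n_map_snps", "length_bp", "first_window", "last_window",
            ],
        )

    def test_regions_within_gap_merged(self):
        r = self._regions(
            [
                ("chr1", 0, 100_000, "desert", 0.01, 12, 12, 100_000, 0, 1),
                ("chr1", 140_000, 240_000, "desert", 0.02, 12, 12, 100_000, 3, 4),
            ]
        )
        out = merge_and_filter(r)
        assert len(out) == 1
        assert out["end_bp"].iloc[0] == 240_000 and out["n_aims"].iloc[0] == 24

    def test_distant_regions_not_merged(self):
        r = self._regions(
            [
                ("chr1", 0, 100_000, "desert", 0.01, 12, 12, 100_000, 0, 1),
                ("chr1", 200_000, 300_000, "desert", 0.02, 12, 12, 100_000, 4, 5),
            ]
        )
        assert len(merge_and_filter(r)) == 2

    @pytest.mark.parametrize(
        "n_aims,n_map,length,kept",
        [
            (9, 12, 100_000, False),  # too few AIMs
            (12, 9, 100_000, False),  # too few map SNPs
            (12, 12, 8_000, False),  # too short
            (10, 10, 10_000, True),  # all at the boundary: kept
        ],
    )
    def test_post_merge_filters(self, n_aims, n_map, length, kept):
        r = self._regions(
            [("chr1", 0, length, "desert", 0.01, n_aims, n_map, length, 0, 0)]
        )
        assert len(merge_and_filter(r)) == (1 if kept else 0)

    def test_mixed_kinds_rejected(self):
        r = self._regions(
            [
                ("chr1", 0, 100_000, "desert", 0.01, 12, 12, 100_000, 0, 1),
                ("chr1", 120_000, 200_000, "island", 0.5, 12, 12, 80_000, 2, 3),
            ]
        )
        with pytest.raises(ValueError, match="mixed"):
            merge_and_filter(r)


class TestSharedRegions:
    def _r(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp"])

    def test_one_bp_overlap_is_shared(self):
        s = shared_regions(self._r([("chr1", 0, 100)]), self._r([("chr1", 99, 200)]))
        assert len(s) == 1 and s["start_bp"].iloc[0] == 99 and s["end_bp"].iloc[0] == 100

    def test_adjacent_half_open_not_shared(self):
        s = shared_regions(self._r([("chr1", 0, 100)]), self._r([("chr1", 100, 200)]))
        assert len(s) == 0

    def test_nested_interval_intersection(self):
        s = shared_regions(self._r([("chr1", 0, 1000)]), self._r([("chr1", 200, 300)]))
        assert s["start_bp"].iloc[0] == 200 and s["end_bp"].iloc[0] == 300


class TestPermutationNulls:
    def _pair(self, seed, n=400):
        rng = np.random.default_rng(seed)
        return (
            _toy_population(rng.beta(2, 6, size=n)),
            _toy_population(rng.beta(2, 6, size=n)),
        )

    def test_observed_sharing_within_null_band_for_independent_data(self):
        pwA, pwB = self._pair(0)
        res = permutation_null_naive(pwA, pwB, n_perm=60, seed=1)
        lo, hi = np.quantile(res["null"], [0.025, 1.0])
        assert res["observed"] <= hi + 2

    def test_p_value_resolution_add_one(self):
        pwA, pwB = self._pair(2)
        res = permutation_null_naive(pwA, pwB, n_perm=50, seed=3)
        assert res["p_value"] >= 1 / 51

    def test_full_rotation_recovers_observed(self):
        pwA, pwB = self._pair(4, n=200)
        from hybridscape.outliers import _shared_count

        regB = merge_and_filter(_detect_runs(pwB, "desert"))
        total_cm = pwA.n * 0.05
        res = permutation_null_shift(pwA, regB, shift_cm=total_cm, n_tilings=1, window_cm=0.05)
        assert res["null"][0] == res["observed"]

    def test_shift_null_preserves_autocorrelation_variance(self):
        """On a strongly autocorrelated signal the shift null has larger
        variance than the naive (iid) null."""
        rng = np.random.default_rng(5)
        n = 400
        ar = np.empty(n)
        ar[0] = 0.2
        for i in range(1, n):  # AR(1), strong autocorrelation
            ar[i] = 0.2 + 0.95 * (ar[i - 1] - 0.2) + 0.01 * rng.normal()
        ar = np.clip(ar, 0, 1)
        pwA = _toy_population(ar)
        pwB = _toy_population(rng.beta(2, 6, size=n))
        regB = merge_and_filter(_detect_runs(pwB, "desert"))
        naive = permutation_null_naive(pwA, pwB, n_perm=80, seed=6)
        shift = permutation_null_shift(pwA, regB, shift_cm=0.5, window_cm=0.05)
        assert shift["null"].var() > naive["null"].var()

    def test_shift_smaller_than_window_rejected(self):
        pwA, pwB = self._pair(7, n=150)
        with pytest.raises(ValueError, match="window"):
            permutation_null_shift(pwA, pwB.windows, shift_cm=0.01, window_cm=0.05)


class TestTimeSeries:
    def test_constant_series_flat_slope(self):
        res = timeseries_trend([2002, 2006, 2017, 2021], [0.1, 0.1, 0.1, 0.1])
        assert res["slope"] == pytest.approx(0.0)

    def test_increasing_series_detected(self):
        years = np.array([2002, 2006, 2017, 2021])
        res = timeseries_trend(years, 0.01 * (years - 2000) + [0.001, -0.001, 0.0005, 0.0])
        assert res["slope"] > 0 and res["p_value"] < 0.05

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError, match="3"):
            timeseries_trend([2002, 2006], [0.1, 0.2])

    def test_drift_only_series_calibrated(self):
        """Binomial resampling with no trend is significant ~5% of the time."""
        rng = np.random.default_rng(8)
        years = np.arange(2000, 2010)
        mat = rng.binomial(200, 0.2, size=(300, len(years))) / 200
        res = timeseries_trends(years, mat, adjust=False)
        frac = (res["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.03


class TestDesertProperties:
    def test_detected_deserts_below_window_threshold(self, small_calls, small_map):
        from hybridscape.outliers import population_windows

        pw = population_windows(small_calls, small_map)
        regions = _detect_runs(pw, "desert")
        for _, r in regions.iterrows():
            assert r["mean_minor_ancestry"] <= pw.quantiles["q10_window"] + 1e-12
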