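"""Minor-parent ancestry deserts and islands.

Deserts (exceptionally low minor-parent ancestry) and islands (exceptionally
high) are seeded at ancestry-informative sites in the 5% tail of the
genome-wide site-level ancestry distribution, confirmed and expanded in
0.05 cM windows while window means stay within the 10% tail, merged when
within 50 kb, filtered (>= 10 AIMs, >= 10 recombination-map SNPs, >= 10 kb),
and overlapped across populations (>= 1 bp).  Significance of cross-population
sharing comes from naive genome-wide window permutations and from circular
shifts in genetic coordinates that preserve local ancestry autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .callset import AncestryCallSet
from .io import make_windows, window_summary
from .maps import RecombMap

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationWindows",
    "population_windows",
    "genome_quantiles",
    "detect_outlier_regions",
    "merge_and_filter",
    "shared_regions",
    "permutation_null_naive",
    "permutation_null_shift",
    "timeseries_trend",
    "timeseries_trends",
]


def genome_quantiles(site_minor: np.ndarray, window_minor: np.ndarray) -> dict:
    """Empirical tail thresholds for outlier detection.

    Seed quantiles (5% tails) come from the per-site distribution of mean
    minor ancestry, expansion quantiles (10% tails) from the 0.05 cM-window
    distribution; both per population.  Linear (type-7) interpolation.
    """
    site = np.asarray(site_minor, dtype=float)
    site = site[np.isfinite(site)]
    win = np.asarray(window_minor, dtype=float)
    win = win[np.isfinite(win)]
    if site.size < 100 or win.size < 100:
        raise ValueError("need >= 100 sites and windows for stable quantiles")
    return {
        "q05_site": float(np.quantile(site, 0.05)),
        "q10_window": float(np.quantile(win, 0.10)),
        "q95_site": float(np.quantile(site, 0.95)),
        "q90_window": float(np.quantile(win, 0.90)),
    }


@dataclass
class PopulationWindows:
    """One population's ancestry summarized on a 0.05 cM window frame.

    ``windows`` rows are genome-ordered; per-window aggregates of site-level
    ancestry (min/max/count) let detection and its permutation nulls run on
    the same window-level code path.
    """

    windows: pd.DataFrame  # chrom/start_bp/end_bp/gstart_cM/gend_cM + stats
    quantiles: dict

    @property
    def n(self) -> int:
        return len(self.windows)

    def permuted(self, rng: np.random.Generator) -> "PopulationWindows":
        """Shuffle window ancestry data genome-wide over the fixed frame."""
        return self._reindexed(rng.permutation(self.n))

    def shifted(self, offset: int) -> "PopulationWindows":
        """Circularly shift window ancestry data by ``offset`` windows."""
        return self._reindexed(np.roll(np.arange(self.n), offset))

    def _reindexed(self, order: np.ndarray) -> "PopulationWindows":
        w = self.windows.copy()
        for col in ("mean_minor_ancestry", "min_site", "max_site", "n_sites", "n_calls"):
            w[col] = self.windows[col].to_numpy()[order]
        return PopulationWindows(w, self.quantiles)


def population_windows(
    calls: AncestryCallSet,
    recomb_map: RecombMap,
    window_cm: float = 0.05,
    quantiles: Optional[dict] = None,
) -> PopulationWindows:
    """Build the 0.05 cM window frame with per-window site aggregates and
    population-specific tail quantiles."""
    frame = make_windows(recomb_map, mode="genetic", size=window_cm)
    frame = window_summary(calls, frame)
    site_minor = calls.site_mean_minor()
    ok = calls.hard_calls >= 0
    n_calls = np.zeros(len(frame), dtype=np.int64)
    min_site = np.full(len(frame), np.nan)
    max_site = np.full(len(frame), np.nan)
    n_map = np.zeros(len(frame), dtype=np.int64)
    for c in frame["chrom"].unique():
        on_c = calls.chrom == c
        pos = calls.pos[on_c]
        vals = site_minor[on_c]
        calls_per_site = ok[:, on_c].sum(axis=0)
        sub = frame.index[frame["chrom"] == c]
        starts = frame.loc[sub, "start_bp"].to_numpy()
        ends = frame.loc[sub, "end_bp"].to_numpy()
        lo = np.searchsorted(pos, starts + 1, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        for w, a, b, s_bp, e_bp in zip(sub, lo, hi, starts, ends):
            n_map[w] = recomb_map.n_map_points(c, s_bp, e_bp)
            if b > a:
                v = vals[a:b]
                v = v[np.isfinite(v)]
                if v.size:
                    min_site[w] = v.min()
                    max_site[w] = v.max()
                n_calls[w] = calls_per_site[a:b].sum()
    frame["min_site"] = min_site
    frame["max_site"] = max_site
    frame["n_calls"] = n_calls
    frame["n_map_snps"] = n_map
    if quantiles is None:
        quantiles = genome_quantiles(site_minor, frame["mean_minor_ancestry"].to_numpy())
    return PopulationWindows(frame, quantiles)


def _detect_runs(pw: PopulationWindows, kind: str) -> pd.DataFrame:
    """Window-level detection core: maximal runs of tail windows containing
    at least one seed window.

    A window is in the tail when its mean is within the 10% window quantile;
    it seeds a region when it additionally contains a site in the 5% site
    tail.  This equals the per-seed bidirectional expansion: the expansion
    from any seed stops exactly at the run boundaries.
    """
    if kind not in ("desert", "island"):
        raise ValueError("kind must be 'desert' or 'island'")
    w = pw.windows
    q = pw.quantiles
    mean = w["mean_minor_ancestry"].to_numpy()
    with np.errstate(invalid="ignore"):
        if kind == "desert":
            in_tail = mean <= q["q10_window"]
            seeds = w["min_site"].to_numpy() <= q["q05_site"]
        else:
            in_tail = mean >= q["q90_window"]
            seeds = w["max_site"].to_numpy() >= q["q95_site"]
    in_tail &= np.isfinite(mean)
    seeds &= in_tail
    chrom = w["chrom"].to_numpy()
    regions = []
    i = 0
    n = len(w)
    while i < n:
        if not in_tail[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_tail[j + 1] and chrom[j + 1] == chrom[i]:
            j += 1
        if seeds[i : j + 1].any():
            regions.append((i, j))
        i = j + 1
    rows = []
    for i, j in regions:
        member = w.iloc[i : j + 1]
        n_calls = member["n_calls"].sum()
        mm = (
            (member["mean_minor_ancestry"] * member["n_calls"]).sum() / n_calls
            if n_calls
            else np.nan
        )
        rows.append(
            {
                "chrom": chrom[i],
                "start_bp": int(member["start_bp"].iloc[0]),
                "end_bp": int(member["end_bp"].iloc[-1]),
                "kind": kind,
                "mean_minor_ancestry": mm,
                "n_aims": int(member["n_sites"].sum()),
                "n_map_snps": int(member["n_map_snps"].sum()),
                "length_bp": int(member["end_bp"].iloc[-1] - member["start_bp"].iloc[0]),
                "first_window": i,
                "last_window": j,
            }
        )
    cols = [
        "chrom",
        "start_bp",
        "end_bp",
        "kind",
        "mean_minor_ancestry",
        "n_aims",
        "n_map_snps",
        "length_bp",
        "first_window",
        "last_window",
    ]
    return pd.DataFrame(rows, columns=cols)


def detect_outlier_regions(
    calls: AncestryCallSet,
    recomb_map: RecombMap,
    kind: str,
    window_cm: float = 0.05,
    quantiles: Optional[dict] = None,
) -> pd.DataFrame:
    """Detect raw (unmerged) ancestry deserts or islands for one population."""
    pw = population_windows(calls, recomb_map, window_cm, quantiles)
    return _detect_runs(pw, kind)


def merge_and_filter(
    regions: pd.DataFrame,
    gap_bp: int = 50_000,
    min_aims: int = 10,
    min_map_snps: int = 10,
    min_len_bp: int = 10_000,
) -> pd.DataFrame:
    """Merge same-kind regions within ``gap_bp`` (transitively) and apply
    the post-merge filters; removal counts are logged."""
    if regions.empty:
        return regions.copy()
    if regions["kind"].nunique() > 1:
        raise ValueError("regions of mixed kinds; merge deserts and islands separately")
    regions = regions.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    merged = []
    cur = regions.iloc[0].to_dict()
    for _, row in regions.iloc[1:].iterrows():
        if row["chrom"] == cur["chrom"] and row["start_bp"] - cur["end_bp"] <= gap_bp:
            w_new = row["n_aims"] + cur["n_aims"]
            if w_new:
                cur["mean_minor_ancestry"] = (
                    cur["mean_minor_ancestry"] * cur["n_aims"]
                    + row["mean_minor_ancestry"] * row["n_aims"]
                ) / w_new
            cur["end_bp"] = row["end_bp"]
            cur["n_aims"] += row["n_aims"]
            cur["n_map_snps"] += row["n_map_snps"]
            cur["last_window"] = row["last_window"]
        else:
            merged.append(cur)
            cur = row.to_dict()
    merged.append(cur)
    out = pd.DataFrame(merged)
    out["length_bp"] = out["end_bp"] - out["start_bp"]
    n0 = len(out)
    keep = (
        (out["n_aims"] >= min_aims)
        & (out["n_map_snps"] >= min_map_snps)
        & (out["length_bp"] >= min_len_bp)
    )
    logger.info(
        "merge_and_filter: %d -> %d merged, %d pass filters", len(regions), n0, keep.sum()
    )
    return out[keep].reset_index(drop=True)


def shared_regions(regionsA: pd.DataFrame, regionsB: pd.DataFrame) -> pd.DataFrame:
    """Region pairs overlapping by >= 1 bp (half-open intervals), with the
    intersection interval."""
    rows = []
    for ia, a in regionsA.iterrows():
        subB = regionsB[regionsB["chrom"] == a["chrom"]]
        for ib, b in subB.iterrows():
            s = max(a["start_bp"], b["start_bp"])
            e = min(a["end_bp"], b["end_bp"])
            if e > s:
                rows.append(
                    {
                        "chrom": a["chrom"],
                        "start_bp": int(s),
                        "end_bp": int(e),
                        "index_a": ia,
                        "index_b": ib,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "index_a", "index_b"])


def _shared_count(pwA: PopulationWindows, pwB: PopulationWindows, kind: str, **filt) -> int:
    ra = merge_and_filter(_detect_runs(pwA, kind), **filt)
    rb = merge_and_filter(_detect_runs(pwB, kind), **filt)
    if ra.empty or rb.empty:
        return 0
    return len(shared_regions(ra, rb))


def permutation_null_naive(
    pwA: PopulationWindows,
    pwB: PopulationWindows,
    kind: str = "desert",
    n_perm: int = 1000,
    seed=None,
    **filt,
) -> dict:
    """Null distribution of cross-population shared-region counts under
    genome-wide shuffling of 0.05 cM window ancestry in both populations.

    Each permutation reruns detection, merging, filtering and overlap
    counting; the empirical p-value for the observed count uses the add-one
    rule, so its resolution is 1/(n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    observed = _shared_count(pwA, pwB, kind, **filt)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        null[i] = _shared_count(pwA.permuted(rng), pwB.permuted(rng), kind, **filt)
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return {"observed": observed, "null": null, "p_value": float(p), "null_mean": float(null.mean())}


def permutation_null_shift(
    pwA: PopulationWindows,
    regionsB: pd.DataFrame,
    kind: str = "desert",
    shift_cm: float = 12.5,
    n_tilings: Optional[int] = None,
    window_cm: float = 0.05,
    **filt,
) -> dict:
    """Shift null: circularly shift population A's window ancestry labels by
    multiples of ``shift_cm`` (in genetic coordinates, wrapping across the
    genome), re-detect outliers, and count overlaps with the fixed regions
    of population B.  Preserves local ancestry autocorrelation.

    ``n_tilings`` defaults to the number of shifts that tiles the genome.
    """
    if shift_cm < window_cm:
        raise ValueError("shift must be at least one window")
    per_shift = int(round(shift_cm / window_cm))
    total_cm = pwA.n * window_cm
    if n_tilings is None:
        n_tilings = max(1, int(np.floor(total_cm / shift_cm)))
    counts = np.empty(n_tilings, dtype=int)
    for k in range(1, n_tilings + 1):
        shifted = pwA.shifted((k * per_shift) % pwA.n)
        ra = merge_and_filter(_detect_runs(shifted, kind), **filt)
        counts[k - 1] = 0 if ra.empty or regionsB.empty else len(shared_regions(ra, regionsB))
    observed = 0
    ra_obs = merge_and_filter(_detect_runs(pwA, kind), **filt)
    if not (ra_obs.empty or regionsB.empty):
        observed = len(shared_regions(ra_obs, regionsB))
    p = (1 + np.sum(counts >= observed)) / (n_tilings + 1)
    return {"observed": observed, "null": counts, "p_value": float(p), "null_mean": float(counts.mean())}


def timeseries_trend(years, values) -> dict:
    """OLS of region mean minor ancestry on sampling year; two-sided slope p."""
    import statsmodels.api as sm

    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 3:
        raise ValueError("need at least 3 sampling years")
    fit = sm.OLS(values, sm.add_constant(years)).fit()
    return {"slope": float(fit.params[1]), "p_value": float(fit.pvalues[1]), "n_years": years.size}


def timeseries_trends(years, value_matrix, alpha: float = 0.05, adjust: bool = True) -> pd.DataFrame:
    """Per-region year trends with optional Benjamini-Hochberg adjustment."""
    from statsmodels.stats.multitest import multipletests

    rows = [timeseries_trend(years, v) for v in np.atleast_2d(value_matrix)]
    df = pd.DataFrame(rows)
    if adjust and len(df):
        df["p_adj"] = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")[1]
    return df
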