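"""Reading, filtering and windowed summarizing of local-ancestry calls.

The window table produced here is the workhorse frame for the correlation,
wavelet and outlier analyses: one row per non-overlapping genomic window
(physical or genetic span) carrying the mean minor-parent ancestry pooled
over (individual, site) hard calls, marker counts, and optional genomic
covariates (recombination rate, coding/conserved basepairs).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .callset import MISSING, AncestryCallSet
from .maps import RecombMap

logger = logging.getLogger(__name__)

__all__ = [
    "hard_call",
    "filter_sites",
    "select_aims",
    "make_windows",
    "window_summary",
    "annotate_windows",
    "thin_windows",
    "read_bed",
    "write_windows",
    "read_windows",
]

WINDOW_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "gstart_cM",
    "gend_cM",
    "mean_minor_ancestry",
    "n_sites",
    "n_individuals_covered",
]


def hard_call(posteriors: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Assign ancestry states from posterior triples.

    The state (0 = homozygous parent 1, 1 = heterozygous, 2 = homozygous
    parent 2) is assigned when its posterior is ``>= threshold`` (the
    threshold itself qualifies); sites where no state reaches the threshold
    are masked (-1).  Triples must sum to 1 within 1e-6.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim == 1:
        post = post[None, :]
    sums = post.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("posterior triples must sum to 1 (tolerance 1e-6)")
    best = post.argmax(axis=-1)
    called = np.take_along_axis(post, best[..., None], axis=-1)[..., 0] >= threshold
    out = np.where(called, best, -1).astype(np.int8)
    return out if np.asarray(posteriors).ndim > 1 else out[0]


def select_aims(
    freq_sp1: np.ndarray,
    freq_sp2: np.ndarray,
    min_diff: float = 0.98,
    f1_hom_confident: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Boolean mask of ancestry-informative sites.

    Retains sites whose allele-frequency difference between the parental
    species is ``>= min_diff``.  ``f1_hom_confident`` (per-site bool) marks
    sites confidently called homozygous in any F1 hybrid, which are
    necessarily genotyping artifacts at a true AIM and are removed.
    """
    f1 = np.asarray(freq_sp1, dtype=float)
    f2 = np.asarray(freq_sp2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("mismatched site lists")
    if np.any((f1 < 0) | (f1 > 1) | (f2 < 0) | (f2 > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    keep = np.abs(f1 - f2) >= min_diff
    if f1_hom_confident is not None:
        keep &= ~np.asarray(f1_hom_confident, dtype=bool)
    return keep


def filter_sites(
    calls: AncestryCallSet,
    min_cover_frac: Optional[float] = 0.25,
    thin_bp: Optional[int] = None,
    end_exclusion_bp: Optional[int] = None,
    repeat_mask: Optional[pd.DataFrame] = None,
    low_power_quantile: Optional[float] = None,
    low_power_window_bp: int = 100_000,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> AncestryCallSet:
    """Remove sites failing any enabled filter; each filter is independently
    switchable by passing ``None``.

    - coverage: sites hard-called in fewer than ``min_cover_frac`` of
      individuals are removed (strictly fewer: a site at exactly the
      threshold is kept);
    - thinning: at most one marker per ``thin_bp`` (the first marker of each
      run is kept, downstream markers closer than ``thin_bp`` are dropped);
    - chromosome ends: sites within ``end_exclusion_bp`` of either end are
      removed (requires ``chrom_lengths``);
    - repeat mask: sites inside masked intervals (BED frame: chrom/start/end,
      0-based half-open) are removed; masks on unknown chromosomes warn;
    - low power: sites in ``low_power_window_bp`` windows whose marker count
      falls in the lower ``low_power_quantile`` tail are removed.

    A per-rule removal count is logged.
    """
    n0 = calls.n_sites
    keep = np.ones(n0, dtype=bool)
    report = {}

    if min_cover_frac is not None:
        ok = calls.site_coverage() >= min_cover_frac
        report["coverage"] = int((~ok & keep).sum())
        keep &= ok

    if end_exclusion_bp is not None:
        if chrom_lengths is None:
            raise ValueError("end exclusion requires chrom_lengths")
        ok = np.ones(n0, dtype=bool)
        for c, L in chrom_lengths.items():
            on_c = calls.chrom == c
            ok[on_c] = (calls.pos[on_c] > end_exclusion_bp) & (
                calls.pos[on_c] <= L - end_exclusion_bp
            )
        report["chrom_ends"] = int((~ok & keep).sum())
        keep &= ok

    if repeat_mask is not None:
        ok = np.ones(n0, dtype=bool)
        known = set(np.unique(calls.chrom))
        for c, sub in repeat_mask.groupby("chrom", sort=False):
            if c not in known:
                logger.warning("repeat mask on unknown chromosome %r ignored", c)
                continue
            on_c = calls.chrom == c
            pos0 = calls.pos[on_c] - 1  # 0-based for half-open BED intervals
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            idx = np.searchsorted(starts, pos0, side="right") - 1
            inside = (idx >= 0) & (pos0 < ends[np.maximum(idx, 0)])
            ok[on_c] = ~inside
        report["repeat_mask"] = int((~ok & keep).sum())
        keep &= ok

    if low_power_quantile is not None:
        win = (calls.pos - 1) // low_power_window_bp
        key = pd.Series(list(zip(calls.chrom[keep], win[keep])))
        counts = key.value_counts()
        thresh = np.quantile(counts.to_numpy(), low_power_quantile)
        bad_windows = set(counts[counts < thresh].index)
        ok = np.array(
            [not ((c, w) in bad_windows) for c, w in zip(calls.chrom, win)], dtype=bool
        )
        report["low_power"] = int((~ok & keep).sum())
        keep &= ok

    if thin_bp is not None:
        ok = np.zeros(n0, dtype=bool)
        for c in calls.chroms:
            idx = np.nonzero((calls.chrom == c) & keep)[0]
            last = -np.inf
            for i in idx:
                if calls.pos[i] - last >= thin_bp:
                    ok[i] = True
                    last = calls.pos[i]
        report["thinning"] = int((keep & ~ok).sum())
        keep &= ok

    logger.info("filter_sites removed per rule: %s (kept %d/%d)", report, keep.sum(), n0)
    out = calls.subset_sites(keep)
    out.filter_report = report  # type: ignore[attr-defined]
    return out


def make_windows(
    recomb_map: RecombMap,
    mode: str = "physical",
    size: float = 100_000,
    chroms: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows.

    ``mode='physical'`` tiles in bp (``size`` in bp); ``mode='genetic'``
    tiles in cM (``size`` in cM) with physical bounds obtained by inverting
    the cumulative map.  The trailing partial window is kept and flagged.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if mode not in ("physical", "genetic"):
        raise ValueError("mode must be 'physical' or 'genetic'")
    rows = []
    for c in chroms or recomb_map.chroms:
        L = recomb_map.chrom_length(c)
        g0 = recomb_map.cum_cm[c][0]
        gL = recomb_map.cum_cm[c][-1]
        if mode == "physical":
            edges = np.arange(0, L, size, dtype=float)
            edges = np.append(edges, L)
        else:
            gedges = np.arange(g0, gL, size, dtype=float)
            gedges = np.append(gedges, gL)
            edges = recomb_map.gen_to_phys(c, gedges)
            edges[0], edges[-1] = 0.0, float(L)
        starts, ends = edges[:-1], edges[1:]
        ok = ends > starts
        starts, ends = starts[ok], ends[ok]
        gstarts = recomb_map.phys_to_gen(c, starts)
        gends = recomb_map.phys_to_gen(c, ends)
        partial = np.zeros(starts.size, dtype=bool)
        if mode == "physical":
            partial[-1] = (ends[-1] - starts[-1]) < size
        else:
            partial[-1] = (gends[-1] - gstarts[-1]) < size * (1 - 1e-9)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "start_bp": starts.astype(np.int64),
                    "end_bp": np.ceil(ends).astype(np.int64),
                    "gstart_cM": gstarts,
                    "gend_cM": gends,
                    "partial": partial,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def window_summary(calls: AncestryCallSet, windows: pd.DataFrame) -> pd.DataFrame:
    """Mean minor-parent ancestry per window.

    The mean pools all non-missing (individual, site) hard calls in the
    window: ``mean(dosage)/2``.  Empty windows get NaN with ``n_sites`` 0.
    """
    out = windows.copy()
    means = np.full(len(out), np.nan)
    n_sites = np.zeros(len(out), dtype=np.int64)
    n_cov = np.zeros(len(out), dtype=np.int64)
    hard = calls.hard_calls
    ok = hard >= 0
    dos = np.where(ok, hard, 0).astype(np.int64)
    for c in out["chrom"].unique():
        on_c = calls.chrom == c
        pos = calls.pos[on_c]
        sub = out.index[out["chrom"] == c]
        # windows are half-open [start, end) in 0-based space; site pos is
        # 1-based, so site p occupies 0-based coordinate p-1
        lo = np.searchsorted(pos, out.loc[sub, "start_bp"].to_numpy() + 1, side="left")
        hi = np.searchsorted(pos, out.loc[sub, "end_bp"].to_numpy(), side="right")
        col_ofs = np.nonzero(on_c)[0]
        for w, a, b in zip(sub, lo, hi):
            if b <= a:
                continue
            cols = col_ofs[a:b]
            n_calls = ok[:, cols].sum()
            n_sites[w] = b - a
            n_cov[w] = int((ok[:, cols].any(axis=1)).sum())
            if n_calls:
                means[w] = dos[:, cols].sum() / (2.0 * n_calls)
            else:
                n_sites[w] = 0
    out["mean_minor_ancestry"] = means
    out["n_sites"] = n_sites
    out["n_individuals_covered"] = n_cov
    return out


def annotate_windows(
    windows: pd.DataFrame,
    recomb_map: Optional[RecombMap] = None,
    bed_tracks: Optional[dict[str, pd.DataFrame]] = None,
) -> pd.DataFrame:
    """Add per-window covariates: mean recombination rate (cM/bp) and the
    number of basepairs covered by each BED track (e.g. coding, conserved)."""
    out = windows.copy()
    if recomb_map is not None:
        rates = np.empty(len(out))
        for i, row in enumerate(out.itertuples()):
            rates[i] = recomb_map.interval_rate(row.chrom, row.start_bp, row.end_bp)
        out["mean_recomb_rate"] = rates
    for name, bed in (bed_tracks or {}).items():
        cov = np.zeros(len(out))
        for c, sub in bed.groupby("chrom", sort=False):
            sel = out["chrom"] == c
            if not sel.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            for i in out.index[sel]:
                a, b = out.at[i, "start_bp"], out.at[i, "end_bp"]
                cov[i] = np.clip(np.minimum(ends, b) - np.maximum(starts, a), 0, None).sum()
        out[f"{name}_bp"] = cov.astype(np.int64)
    return out


def thin_windows(
    table: pd.DataFrame,
    spacing_bp: Optional[float] = None,
    spacing_cm: Optional[float] = None,
) -> pd.DataFrame:
    """Keep the first window of each spacing block per chromosome.

    Exactly one of ``spacing_bp`` (e.g. 1 Mb) or ``spacing_cm`` (e.g. 1.5 cM)
    must be given.  Blocks are laid out in genome coordinates, so windows
    already dropped upstream do not shift the blocks.
    """
    if (spacing_bp is None) == (spacing_cm is None):
        raise ValueError("give exactly one of spacing_bp / spacing_cm")
    if spacing_bp is not None:
        block = (table["start_bp"] // spacing_bp).astype(int)
    else:
        block = (table["gstart_cM"] / spacing_cm).astype(int)
    key = pd.DataFrame({"chrom": table["chrom"], "block": block}, index=table.index)
    first = key.groupby(["chrom", "block"], sort=False).head(1).index
    return table.loc[table.index.isin(first)].copy()


# ---------------------------------------------------------------------------
# plain-text I/O

def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end (+name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in df.columns:
        df = df.rename(columns={3: "name"})
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_windows(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_windows(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values="NA")
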