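"""Ancestry transitions: historical recombination events in hybrid genomes.

A transition is the interval over which an individual's diploid ancestry
track changes from one confidently called state to another — the posterior
drops below the hard-call threshold for the old state and rises to it for
the new one.  Transition locations across individuals feed an ordination
(shared history would cluster individuals), and the rate of cross-population
transition sharing is compared against a null that re-places each transition
at random, weighted by the recombination map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .callset import AncestryCallSet
from .maps import RecombMap

__all__ = [
    "TransitionSet",
    "extract_transitions",
    "transition_window_matrix",
    "count_shared_transitions",
    "simulate_transition_placement",
    "transition_pca",
]


@dataclass
class TransitionSet:
    """Per-individual transition intervals.

    ``table`` columns: individual, chrom, start_bp, end_bp (half-open, the
    uncertainty interval of the underlying recombination breakpoint),
    from_state, to_state (diploid minor dosage).  ``resolution`` is
    end - start.
    """

    table: pd.DataFrame
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.table):
            bad = self.table["start_bp"] >= self.table["end_bp"]
            if bad.any():
                raise ValueError("transition intervals must satisfy start < end")
            if (self.table["from_state"] == self.table["to_state"]).any():
                raise ValueError("from_state must differ from to_state")

    def __len__(self) -> int:
        return len(self.table)

    def for_individual(self, ind: str) -> pd.DataFrame:
        return self.table[self.table["individual"] == ind]

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["start_bp"] -= 1  # emit 0-based half-open, BED-like
        out.to_csv(path, sep="\t", index=False)


def extract_transitions(
    calls: AncestryCallSet,
    min_flank_bp: int = 5_000,
) -> TransitionSet:
    """Extract ancestry transitions from hard-called diploid tracks.

    The transition interval runs from the last site confidently supporting
    the old state to the first site confidently supporting the new state.
    Transitions flanked by a confident same-state segment shorter than
    ``min_flank_bp`` on either side are removed — this drops
    switch-and-immediately-revert artifacts.  A dosage change of 2 (0 to 2
    with no intermediate heterozygous site) is one transition.
    """
    rows = []
    any_calls = False
    for i, ind in enumerate(calls.individuals):
        for c in calls.chroms:
            on_c = calls.chrom == c
            pos = calls.pos[on_c]
            hard = calls.hard_calls[i, on_c]
            ok = hard >= 0
            if not ok.any():
                continue
            any_calls = True
            p = pos[ok]
            s = hard[ok]
            change = np.nonzero(s[1:] != s[:-1])[0]
            if change.size == 0:
                continue
            # runs of constant confident state; run r spans sites
            # [bounds[r], bounds[r+1])
            bounds = np.concatenate([[0], change + 1, [s.size]])
            span = p[bounds[1:] - 1] - p[bounds[:-1]]
            n_runs = span.size
            for t, idx in enumerate(change):
                # edge runs extend beyond the observed track and always count
                # as supported; internal runs need min_flank_bp of extent
                left_ok = t == 0 or span[t] >= min_flank_bp
                right_ok = t + 1 == n_runs - 1 or span[t + 1] >= min_flank_bp
                if not (left_ok and right_ok):
                    continue
                rows.append(
                    {
                        "individual": ind,
                        "chrom": c,
                        "start_bp": int(p[idx]),
                        "end_bp": int(p[idx + 1]),
                        "from_state": int(s[idx]),
                        "to_state": int(s[idx + 1]),
                    }
                )
    if not any_calls:
        raise ValueError("all hard calls missing")
    cols = ["individual", "chrom", "start_bp", "end_bp", "from_state", "to_state"]
    return TransitionSet(pd.DataFrame(rows, columns=cols), list(calls.individuals))


def transition_window_matrix(tset: TransitionSet, windows: pd.DataFrame) -> pd.DataFrame:
    """Binary individuals x windows indicator of transition presence.

    Multi-window transitions are placed at their interval midpoint; multiple
    transitions in one window still give a single 1.  ``windows`` is a
    genetic-distance frame (0.5 cM) from :func:`hybridscape.io.make_windows`.
    """
    mat = np.zeros((len(tset.individuals), len(windows)), dtype=np.int8)
    ind_idx = {ind: k for k, ind in enumerate(tset.individuals)}
    win = windows.reset_index(drop=True)
    for c in win["chrom"].unique():
        sub = win[win["chrom"] == c]
        starts = sub["start_bp"].to_numpy()
        tc = tset.table[tset.table["chrom"] == c]
        if tc.empty:
            continue
        mid = ((tc["start_bp"] + tc["end_bp"]) // 2).to_numpy()
        w = np.searchsorted(starts, mid, side="right") - 1
        w = np.clip(w, 0, len(sub) - 1)
        inside = mid < sub["end_bp"].to_numpy()[w]
        cols = sub.index.to_numpy()[w]
        for ind, col, ins in zip(tc["individual"], cols, inside):
            if ins:
                mat[ind_idx[ind], col] = 1
    return pd.DataFrame(mat, index=tset.individuals, columns=win.index)


def count_shared_transitions(
    setA: TransitionSet,
    setB: TransitionSet,
    max_len_bp: int = 250_000,
) -> pd.DataFrame:
    """Shared transition counts for every cross-population individual pair.

    Poorly resolved transitions (interval longer than ``max_len_bp``) are
    excluded first; two transitions are shared when their intervals overlap
    by at least 1 bp.
    """

    def usable(ts: TransitionSet) -> pd.DataFrame:
        t = ts.table
        return t[(t["end_bp"] - t["start_bp"]) <= max_len_bp]

    ta, tb = usable(setA), usable(setB)
    rows = []
    for a_ind in setA.individuals:
        a_sub = ta[ta["individual"] == a_ind]
        for b_ind in setB.individuals:
            b_sub = tb[tb["individual"] == b_ind]
            n = 0
            for c in set(a_sub["chrom"]) & set(b_sub["chrom"]):
                ac = a_sub[a_sub["chrom"] == c]
                bc = b_sub[b_sub["chrom"] == c]
                s1 = ac["start_bp"].to_numpy()[:, None]
                e1 = ac["end_bp"].to_numpy()[:, None]
                s2 = bc["start_bp"].to_numpy()[None, :]
                e2 = bc["end_bp"].to_numpy()[None, :]
                n += int(((np.minimum(e1, e2) - np.maximum(s1, s2)) > 0).sum())
            rows.append({"individual_a": a_ind, "individual_b": b_ind, "shared": n})
    return pd.DataFrame(rows, columns=["individual_a", "individual_b", "shared"])


def simulate_transition_placement(
    tset: TransitionSet,
    recomb_map: RecombMap,
    map_window_bp: int = 100_000,
    fixed_windows: Optional[pd.DataFrame] = None,
    seed=None,
) -> TransitionSet:
    """Re-place every transition at a random genomic location weighted by
    the recombination map summarized in ``map_window_bp`` windows.

    Windows where ancestry has fixed (``fixed_windows``: chrom/start/end
    frame) are excluded and the sampling probabilities renormalized.  For
    each transition a window is drawn with probability proportional to its
    genetic length, the start position uniformly within the window, and the
    interval length preserved exactly (shifted left if it would run off the
    chromosome); per-individual transition counts are unchanged.
    """
    rng = np.random.default_rng(seed)
    wins = []
    for c in recomb_map.chroms:
        L = recomb_map.chrom_length(c)
        starts = np.arange(0, L, map_window_bp)
        ends = np.minimum(starts + map_window_bp, L)
        g = recomb_map.phys_to_gen(c, np.append(starts, L))
        rate = np.diff(g)
        wins.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends, "gen_len": rate}))
    wins = pd.concat(wins, ignore_index=True)
    if fixed_windows is not None and len(fixed_windows):
        drop = np.zeros(len(wins), dtype=bool)
        for _, f in fixed_windows.iterrows():
            drop |= (
                (wins["chrom"] == f["chrom"])
                & (wins["start"] < f["end"])
                & (wins["end"] > f["start"])
            )
        wins = wins[~drop].reset_index(drop=True)
    weights = wins["gen_len"].to_numpy()
    if weights.sum() <= 0:
        raise ValueError("no recombination mass in admissible windows")
    probs = weights / weights.sum()
    chrom_len = {c: recomb_map.chrom_length(c) for c in recomb_map.chroms}
    max_L = max(chrom_len.values())

    t = tset.table
    lengths = (t["end_bp"] - t["start_bp"]).to_numpy()
    if lengths.size and lengths.max() > max_L:
        raise ValueError("transition interval longer than any chromosome")
    idx = rng.choice(len(wins), size=len(t), p=probs)
    w_start = wins["start"].to_numpy()[idx]
    w_end = wins["end"].to_numpy()[idx]
    w_chrom = wins["chrom"].to_numpy()[idx]
    starts = w_start + np.floor(rng.random(len(t)) * (w_end - w_start)).astype(np.int64)
    ends = starts + lengths
    # preserve length: shift intervals that would run off the chromosome
    for k in range(len(t)):
        L = chrom_len[w_chrom[k]]
        if ends[k] > L:
            shift = ends[k] - L
            starts[k] -= shift
            ends[k] = L
            if starts[k] < 0:
                raise ValueError("transition interval longer than any admissible span")
    out = t.copy()
    out["chrom"] = w_chrom
    out["start_bp"] = starts
    out["end_bp"] = ends
    return TransitionSet(out.reset_index(drop=True), list(tset.individuals))


def transition_pca(matrix: pd.DataFrame, n_components: int = 2):
    """Principal components of the transition indicator matrix (column
    mean-centered, unscaled — binary data).  Returns (scores, explained
    variance ratio)."""
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    var = S**2 / max(1, X.shape[0] - 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    return U[:, :k] * S[:k], ratio[:k]
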