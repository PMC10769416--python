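"""Pairwise homozygous-mismatch statistic within shared ancestry tracts.

Populations founded from distinct source populations carry different variant
frequencies even inside tracts of the same ancestry.  Restricting to genomic
segments where a panel of hybrids is confidently homozygous for one parental
ancestry, the mismatch statistic for a pair of individuals is the fraction
of jointly passing sites at which the two are homozygous for different
alleles — near zero for close relatives, rising with source-population
divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .callset import AncestryCallSet

__all__ = ["GenotypeTable", "shared_homozygous_tracts", "pairwise_mismatch"]


@dataclass
class GenotypeTable:
    """Biallelic genotypes (0/1/2 alt-allele dosage, -1 missing) at 1-based
    positions, with a per-site quality pass flag (variant-filter verdicts
    from upstream calling)."""

    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray  # (n_ind, n_sites) int8
    site_pass: np.ndarray  # (n_sites,) bool
    individuals: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.site_pass = np.asarray(self.site_pass, dtype=bool)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError("positions must be sorted within chromosomes")
        if not np.isin(self.genotypes, [-1, 0, 1, 2]).all():
            raise ValueError("genotypes must be in {0,1,2,-1}")

    def column(self, ind: str) -> np.ndarray:
        return self.genotypes[self.individuals.index(ind)]


def shared_homozygous_tracts(calls: AncestryCallSet, state: int) -> pd.DataFrame:
    """Maximal intervals where every panel member is confidently homozygous
    for the requested ancestry.

    ``state`` is the minor-ancestry dosage that qualifies (0 = homozygous
    major parent, 2 = homozygous minor parent).  Confidence is the hard call
    itself (0.9 posterior threshold upstream).  Intervals are emitted in
    BED-style half-open coordinates spanning from the first to one past the
    last qualifying site of each run.
    """
    if calls.n_individuals == 0:
        raise ValueError("empty panel")
    if state not in (0, 2):
        raise ValueError("state must be homozygous (0 or 2)")
    qual = (calls.hard_calls == state).all(axis=0)
    rows = []
    for c in calls.chroms:
        on_c = calls.chrom == c
        pos = calls.pos[on_c]
        q = qual[on_c]
        if not q.any():
            continue
        change = np.nonzero(q[1:] != q[:-1])[0]
        bounds = np.concatenate([[0], change + 1, [q.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if q[a]:
                rows.append({"chrom": c, "start": int(pos[a]) - 1, "end": int(pos[b - 1])})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _in_tracts(chrom: np.ndarray, pos: np.ndarray, tracts: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(pos.size, dtype=bool)
    for c, sub in tracts.groupby("chrom", sort=False):
        on_c = chrom == c
        p0 = pos[on_c] - 1  # 0-based against half-open tracts
        starts = np.sort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())]
        idx = np.searchsorted(starts, p0, side="right") - 1
        inside = (idx >= 0) & (p0 < ends[np.maximum(idx, 0)])
        mask[on_c] = inside
    return mask


def pairwise_mismatch(
    genotypes: GenotypeTable,
    ind_a: str,
    ind_b: str,
    tracts: pd.DataFrame,
) -> dict:
    """Homozygous-mismatch statistic for one pair of individuals.

    numerator: sites inside ``tracts`` where one individual is homozygous
    reference and the other homozygous alternate; denominator: sites inside
    the tracts passing quality in both individuals (non-missing and site
    pass flag).  Heterozygous sites count toward the denominator but never
    the numerator.
    """
    if tracts.empty:
        raise ValueError("no tracts supplied")
    ga = genotypes.column(ind_a)
    gb = genotypes.column(ind_b)
    inside = _in_tracts(genotypes.chrom, genotypes.pos, tracts)
    passing = inside & genotypes.site_pass & (ga >= 0) & (gb >= 0)
    n_pass = int(passing.sum())
    if n_pass == 0:
        raise ValueError("no jointly passing sites in tracts")
    opposite = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
    n_mm = int((opposite & passing).sum())
    return {
        "mismatch": n_mm / n_pass,
        "n_mismatch": n_mm,
        "n_passing": n_pass,
        "pair": (ind_a, ind_b),
    }


def mismatch_matrix(genotypes: GenotypeTable, tracts: pd.DataFrame, pairs: Sequence[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Mismatch statistic for every requested (default: all) pair."""
    inds = genotypes.individuals
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(inds) for b in inds[i + 1 :]]
    return pd.DataFrame([pairwise_mismatch(genotypes, a, b, tracts) for a, b in pairs])
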