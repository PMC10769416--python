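"""Recombination maps: monotone physical <-> genetic coordinate conversion.

A :class:`RecombMap` stores, per chromosome, sorted physical positions (bp,
0-based) with the cumulative genetic position (cM) at each point.  Rates
between map points are piecewise constant; conversion in either direction is
linear interpolation.  The map points double as the "SNPs present in the
recombination map" used when filtering outlier regions, mirroring the
LD-based maps such analyses are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RecombMap"]


@dataclass
class RecombMap:
    """Per-chromosome physical (bp) to genetic (cM) coordinate map.

    Parameters
    ----------
    positions : dict of chrom -> array of bp positions (sorted, first 0)
    cum_cm : dict of chrom -> array of cumulative cM (non-decreasing)
    """

    positions: dict[str, np.ndarray]
    cum_cm: dict[str, np.ndarray]
    chroms: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.chroms = list(self.positions)
        for c in self.chroms:
            pos = np.asarray(self.positions[c], dtype=float)
            cm = np.asarray(self.cum_cm[c], dtype=float)
            if pos.shape != cm.shape or pos.size < 2:
                raise ValueError(f"map for {c!r} needs >= 2 (pos, cM) points")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"map positions for {c!r} not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cumulative cM for {c!r} decreases")
            self.positions[c] = pos
            self.cum_cm[c] = cm

    # -- constructors ------------------------------------------------------
    @classmethod
    def uniform(
        cls,
        chrom_lengths: dict[str, int],
        rate_cm_per_mb: float = 1.0,
        node_spacing_bp: int | None = None,
    ) -> "RecombMap":
        """Uniform-rate map.  ``node_spacing_bp`` adds interior map points
        (emulating the SNP density of an empirical map)."""
        positions, cum = {}, {}
        for c, L in chrom_lengths.items():
            if node_spacing_bp:
                pos = np.arange(0, L + 1, node_spacing_bp, dtype=float)
                if pos[-1] != L:
                    pos = np.append(pos, L)
            else:
                pos = np.array([0.0, float(L)])
            positions[c] = pos
            cum[c] = pos * rate_cm_per_mb / 1e6
        return cls(positions, cum)

    @classmethod
    def read_tsv(cls, path) -> "RecombMap":
        """Read a tab-delimited map: columns chrom, pos_bp, cum_cM."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        positions = {}
        cum = {}
        for c, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos_bp")
            positions[str(c)] = sub["pos_bp"].to_numpy(dtype=float)
            cum[str(c)] = sub["cum_cM"].to_numpy(dtype=float)
        return cls(positions, cum)

    def write_tsv(self, path) -> None:
        rows = []
        for c in self.chroms:
            rows.append(
                pd.DataFrame(
                    {"chrom": c, "pos_bp": self.positions[c], "cum_cM": self.cum_cm[c]}
                )
            )
        pd.concat(rows).to_csv(path, sep="\t", index=False)

    # -- conversions -------------------------------------------------------
    def chrom_length(self, chrom: str) -> int:
        return int(self.positions[chrom][-1])

    def chrom_length_cm(self, chrom: str) -> float:
        return float(self.cum_cm[chrom][-1] - self.cum_cm[chrom][0])

    def total_length_cm(self) -> float:
        return float(sum(self.chrom_length_cm(c) for c in self.chroms))

    def phys_to_gen(self, chrom: str, bp) -> np.ndarray:
        return np.interp(np.asarray(bp, dtype=float), self.positions[chrom], self.cum_cm[chrom])

    def gen_to_phys(self, chrom: str, cm) -> np.ndarray:
        """Invert the cumulative map.  Flat (zero-rate) stretches map to their
        left edge, which keeps the inverse a function."""
        cum = self.cum_cm[chrom]
        pos = self.positions[chrom]
        cm = np.asarray(cm, dtype=float)
        # np.interp requires strictly increasing xp on ties -> collapse them
        keep = np.concatenate([[True], np.diff(cum) > 0])
        return np.interp(cm, cum[keep], pos[keep])

    def interval_rate(self, chrom: str, start_bp: float, end_bp: float) -> float:
        """Mean rate (cM/bp) over [start_bp, end_bp)."""
        if end_bp <= start_bp:
            raise ValueError("empty interval")
        g = self.phys_to_gen(chrom, [start_bp, end_bp])
        return float((g[1] - g[0]) / (end_bp - start_bp))

    def n_map_points(self, chrom: str, start_bp: float, end_bp: float) -> int:
        pos = self.positions[chrom]
        return int(np.searchsorted(pos, end_bp) - np.searchsorted(pos, start_bp))
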