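"""Container for per-individual local-ancestry calls at ancestry-informative sites.

An :class:`AncestryCallSet` holds, for a sample of diploid hybrids, the
posterior probabilities of the three ancestry states at each informative site
(homozygous parent-1, heterozygous, homozygous parent-2) together with
hard calls expressed as minor-parent ancestry dosage (0/1/2, -1 = missing).
Sites are 1-based marker positions; the container is the in-memory form of
the tab-delimited posterior tracks an ancestry HMM emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AncestryCallSet", "MISSING"]

MISSING = np.int8(-1)


@dataclass
class AncestryCallSet:
    chrom: np.ndarray  # (n_sites,) str, sorted by (chrom, pos)
    pos: np.ndarray  # (n_sites,) int, 1-based
    posteriors: np.ndarray  # (n_ind, n_sites, 3) float: P11, P12, P22
    hard_calls: np.ndarray  # (n_ind, n_sites) int8 minor dosage, -1 missing
    minor_parent: int  # 0 = parent1 is minor, 1 = parent2 is minor
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.posteriors = np.asarray(self.posteriors, dtype=np.float64)
        self.hard_calls = np.asarray(self.hard_calls, dtype=np.int8)
        if not self.individuals:
            self.individuals = [f"ind{i}" for i in range(self.hard_calls.shape[0])]
        if self.posteriors.shape[:2] != self.hard_calls.shape:
            raise ValueError("posteriors and hard_calls shapes disagree")
        if self.minor_parent not in (0, 1):
            raise ValueError("minor_parent must be 0 or 1")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.hard_calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.hard_calls.shape[1]

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.chrom))

    def sites_of(self, chrom: str) -> np.ndarray:
        return self.pos[self.chrom == chrom]

    # -- state <-> dosage --------------------------------------------------
    def state_to_minor_dosage(self, state: np.ndarray) -> np.ndarray:
        """Map ancestry state (copies of parent2: 0,1,2) to minor dosage."""
        state = np.asarray(state)
        out = np.where(state < 0, MISSING, state if self.minor_parent == 1 else 2 - state)
        return out.astype(np.int8)

    # -- summaries ---------------------------------------------------------
    def site_coverage(self) -> np.ndarray:
        """Fraction of individuals with a non-missing call at each site."""
        return (self.hard_calls >= 0).mean(axis=0)

    def site_mean_minor(self) -> np.ndarray:
        """Per-site mean minor ancestry (dosage/2) over non-missing calls."""
        ok = self.hard_calls >= 0
        n = ok.sum(axis=0)
        s = np.where(ok, self.hard_calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, s / (2.0 * n), np.nan)

    def individual_mean_minor(self) -> np.ndarray:
        ok = self.hard_calls >= 0
        n = ok.sum(axis=1)
        s = np.where(ok, self.hard_calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, s / (2.0 * n), np.nan)

    # -- subsetting --------------------------------------------------------
    def subset_sites(self, mask: np.ndarray) -> "AncestryCallSet":
        mask = np.asarray(mask)
        return AncestryCallSet(
            self.chrom[mask],
            self.pos[mask],
            self.posteriors[:, mask],
            self.hard_calls[:, mask],
            self.minor_parent,
            list(self.individuals),
        )

    def subset_individuals(self, idx) -> "AncestryCallSet":
        idx = np.asarray(idx)
        return AncestryCallSet(
            self.chrom,
            self.pos,
            self.posteriors[idx],
            self.hard_calls[idx],
            self.minor_parent,
            [self.individuals[i] for i in idx],
        )

    # -- I/O ---------------------------------------------------------------
    def to_posterior_frame(self) -> pd.DataFrame:
        """Wide posterior-track frame: chrom, pos, then <ind>:p11/p12/p22."""
        data = {"chrom": self.chrom, "pos": self.pos}
        for i, ind in enumerate(self.individuals):
            for k, tag in enumerate(("p11", "p12", "p22")):
                data[f"{ind}:{tag}"] = self.posteriors[i, :, k]
        return pd.DataFrame(data)

    def write_posteriors(self, path) -> None:
        self.to_posterior_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_hard_calls(self, path) -> None:
        data = {"chrom": self.chrom, "pos": self.pos}
        for i, ind in enumerate(self.individuals):
            col = self.hard_calls[i].astype(float)
            col[col < 0] = np.nan
            data[ind] = col
        pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_posteriors(cls, path, minor_parent: int, threshold: float = 0.9) -> "AncestryCallSet":
        """Read a wide posterior-track TSV written by :meth:`write_posteriors`.

        Hard calls are regenerated at ``threshold`` (see
        :func:`hybridscape.io.hard_call`)."""
        from .io import hard_call  # local import to avoid a cycle

        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        inds = []
        for col in df.columns[2:]:
            name = col.rsplit(":", 1)[0]
            if name not in inds:
                inds.append(name)
        n_sites = len(df)
        post = np.empty((len(inds), n_sites, 3))
        for i, ind in enumerate(inds):
            for k, tag in enumerate(("p11", "p12", "p22")):
                post[i, :, k] = df[f"{ind}:{tag}"].to_numpy()
        states = np.stack([hard_call(post[i], threshold) for i in range(len(inds))])
        obj = cls(
            df["chrom"].to_numpy(),
            df["pos"].to_numpy(),
            post,
            np.zeros((len(inds), n_sites), dtype=np.int8),
            minor_parent,
            inds,
        )
        obj.hard_calls = obj.state_to_minor_dosage(states)
        return obj
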