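"""Rank-correlation analyses of windowed ancestry.

Spearman and partial Spearman correlations between minor-parent ancestry and
genomic covariates, cross-population correlation with genome-coordinate
thinning, a resampling depletion test for candidate regions (e.g. inversion
centers) with an optional low-recombination stratified null, and the
Hardy-Weinberg expectation for incompatible-embryo production.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import thin_windows

__all__ = [
    "CorrelationResult",
    "spearman",
    "partial_spearman",
    "cross_population_correlation",
    "region_depletion_test",
    "hwe_incompatible_fraction",
]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    covariates: int = 0
    thinning: Optional[str] = None

    def __post_init__(self) -> None:
        if not -1.0000001 <= self.rho <= 1.0000001:
            raise ValueError("correlation out of range")


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite (drop missing values first)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (midranks for ties, t-approximation p)."""
    x, y = _check_xy(x, y)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), x.size)


def partial_spearman(x, y, covariates) -> CorrelationResult:
    """Spearman partial correlation controlling for covariates.

    All variables are rank-transformed (midranks); x and y ranks are
    residualized on the covariate ranks (with intercept) by least squares and
    the residuals correlated.  For one covariate this equals the recursive
    partial-correlation formula on rank correlations.  The p-value uses the
    t-approximation with ``n - 2 - k`` degrees of freedom.
    """
    x, y = _check_xy(x, y)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] == x.size and Z.ndim == 2:
        pass
    elif Z.shape[1] == x.size:
        Z = Z.T
    else:
        raise ValueError("covariate shape does not match x")
    k = Z.shape[1]
    if k == 0:
        return spearman(x, y)
    if x.size < k + 3:
        raise ValueError("need at least covariates + 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([stats.rankdata(Z[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(x.size), rz])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    ssx, ssy = (ex**2).sum(), (ey**2).sum()
    # a variable fully explained by the covariates has no residual signal:
    # the partial correlation is 0 (guard against float-noise residuals)
    tiny = 1e-10 * rx.var() * x.size
    if ssx < tiny or ssy < tiny:
        rho = 0.0
    else:
        rho = float((ex * ey).sum() / np.sqrt(ssx * ssy))
    df = x.size - 2 - k
    rho_c = np.clip(rho, -0.9999999999, 0.9999999999)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(rho, p, x.size, covariates=k)


def cross_population_correlation(
    tableA: pd.DataFrame,
    tableB: pd.DataFrame,
    spacing_bp: Optional[float] = None,
    spacing_cm: Optional[float] = None,
) -> CorrelationResult:
    """Spearman correlation of mean minor ancestry between two populations
    summarized on the same window frame, after thinning to one window per
    spacing block (admixture LD decays below the 1 Mb / 1.5 cM spacings)."""
    keys = ["chrom", "start_bp"]
    joined = tableA.merge(tableB, on=keys, suffixes=("_a", "_b"))
    joined = joined.dropna(subset=["mean_minor_ancestry_a", "mean_minor_ancestry_b"])
    if spacing_bp is not None or spacing_cm is not None:
        joined = joined.rename(columns={"gstart_cM_a": "gstart_cM"})
        joined = thin_windows(joined, spacing_bp=spacing_bp, spacing_cm=spacing_cm)
        thinning = f"{spacing_bp} bp" if spacing_bp else f"{spacing_cm} cM"
    else:
        thinning = None
    if len(joined) < 3:
        raise ValueError("fewer than 3 shared non-missing windows")
    res = spearman(
        joined["mean_minor_ancestry_a"].to_numpy(),
        joined["mean_minor_ancestry_b"].to_numpy(),
    )
    res.thinning = thinning
    return res


def region_depletion_test(
    table: pd.DataFrame,
    regions: pd.DataFrame,
    probe_bp: int = 50_000,
    n_resamples: int = 1000,
    null: str = "genome",
    low_recomb_quantile: float = 0.05,
    seed=None,
) -> dict:
    """Depletion of minor ancestry at region centers vs resampled probes.

    Observed statistic: mean of window-table ancestry interpolated at a
    ``probe_bp`` window centered on each region's midpoint.  The null draws
    ``n_resamples`` sets of random probe centers, either genome-wide
    (``null='genome'``) or restricted to windows in the lowest
    ``low_recomb_quantile`` tail of recombination rate
    (``null='low_recomb_5pct'``), and the empirical p-value uses the add-one
    rule: p = (1 + #{null <= observed}) / (n_resamples + 1).
    """
    rng = np.random.default_rng(seed)
    tab = table.dropna(subset=["mean_minor_ancestry"]).reset_index(drop=True)
    if null == "low_recomb_5pct":
        if "mean_recomb_rate" not in tab.columns:
            raise ValueError("stratified null needs a mean_recomb_rate column")
        cut = tab["mean_recomb_rate"].quantile(low_recomb_quantile)
        pool = tab[tab["mean_recomb_rate"] <= cut].reset_index(drop=True)
        if pool.empty:
            raise ValueError("low-recombination stratum is empty")
    elif null == "genome":
        pool = tab
    else:
        raise ValueError("null must be 'genome' or 'low_recomb_5pct'")

    def probe_mean(chroms, centers):
        vals = []
        for c, mid in zip(chroms, centers):
            sub = tab[tab["chrom"] == c]
            sel = (sub["end_bp"] > mid - probe_bp / 2) & (sub["start_bp"] < mid + probe_bp / 2)
            if sel.any():
                vals.append(sub.loc[sel, "mean_minor_ancestry"].mean())
        return float(np.mean(vals)) if vals else np.nan

    centers = ((regions["start"] + regions["end"]) / 2).to_numpy()
    observed = probe_mean(regions["chrom"].to_numpy(), centers)
    k = len(regions)
    null_means = np.empty(n_resamples)
    pool_mid = ((pool["start_bp"] + pool["end_bp"]) / 2).to_numpy()
    pool_chrom = pool["chrom"].to_numpy()
    for i in range(n_resamples):
        idx = rng.integers(0, len(pool), size=k)
        null_means[i] = probe_mean(pool_chrom[idx], pool_mid[idx])
    p = (1 + np.sum(null_means <= observed)) / (n_resamples + 1)
    return {
        "observed": observed,
        "null_mean": float(np.nanmean(null_means)),
        "null": null_means,
        "p_value": float(p),
        "n_regions": k,
    }


def hwe_incompatible_fraction(p_minor: float) -> float:
    """Expected fraction of offspring homozygous for minor ancestry at an
    incompatible locus under Hardy-Weinberg equilibrium (``p_minor**2``),
    i.e. matings producing incompatible embryos on a fixed mismatched
    mitochondrial background."""
    if not 0.0 <= p_minor <= 1.0:
        raise ValueError("p_minor must be in [0, 1]")
    return float(p_minor) ** 2
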