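"""Approximate Bayesian computation for hybrid-population demography.

Rejection ABC with local-linear regression adjustment (Beaumont-style, as in
ABCreg): demographic parameters (initial admixture proportion, hybrid
population size, time since admixture, migration rates from both parents)
are drawn from priors, forward simulations produce summary statistics
(genome-wide admixture proportion, coefficients of variation of genome-wide
and local ancestry, median minor-parent tract length), and the draws whose
statistics fall nearest the observed data — after median-absolute-deviation
standardization — are accepted and regression-adjusted to the observed
point.  Posterior modes (MAP) come from a Gaussian kernel density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .callset import AncestryCallSet
from .simulate import (
    PARENT2,
    SimConfig,
    mean_ancestry,
    simulate_hybrid_population,
    summarize_tracts,
    tracts_to_calls,
)

__all__ = [
    "PriorSpec",
    "SummaryStats",
    "summary_stats",
    "run_reference_table",
    "abc_reject_regress",
    "map_estimate",
    "coverage_validation",
]

PARAM_NAMES = ["p0", "N_hybrid", "t_admix", "m1", "m2"]
STAT_NAMES = ["admix_prop", "cv_genomewide", "cv_local", "median_minor_tract_bp"]
LOG_PARAMS = {"m1", "m2"}  # log-uniform priors are regressed on log scale


@dataclass
class PriorSpec:
    """Priors on hybrid-population demography.

    p0 ~ U(0.5, 1); N ~ U(2, 10,000) (integer); t ~ U(10, 400) generations;
    m1, m2 ~ log-uniform up to 0.03 per generation.  A log-uniform prior
    cannot start at zero; the lower bound defaults to 1e-6, below the
    smallest migration rate such data can resolve.
    """

    p0: tuple[float, float] = (0.5, 1.0)
    N_hybrid: tuple[int, int] = (2, 10_000)
    t_admix: tuple[int, int] = (10, 400)
    m_upper: float = 0.03
    m_lower: float = 1e-6

    def bounds(self, name: str) -> tuple[float, float]:
        if name in LOG_PARAMS:
            return (self.m_lower, self.m_upper)
        return getattr(self, name)

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = self.N_hybrid
        draw = {
            "p0": rng.uniform(*self.p0),
            "N_hybrid": int(rng.integers(lo, hi + 1)),
            "t_admix": int(rng.integers(self.t_admix[0], self.t_admix[1] + 1)),
        }
        for m in ("m1", "m2"):
            draw[m] = float(
                np.exp(rng.uniform(np.log(self.m_lower), np.log(self.m_upper)))
            )
        return draw


@dataclass
class SummaryStats:
    admix_prop: float  # genome-wide minor-parent admixture proportion
    cv_genomewide: float  # CV of individual genome-wide ancestry
    cv_local: float  # CV of local (windowed) ancestry
    median_minor_tract_bp: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.admix_prop, self.cv_genomewide, self.cv_local, self.median_minor_tract_bp]
        )


def _cv(x: np.ndarray) -> float:
    m = np.nanmean(x)
    return float(np.nanstd(x) / m) if m > 0 else 0.0


def summary_stats(calls: AncestryCallSet, window_bp: int = 100_000, tract_median_bp: Optional[float] = None) -> SummaryStats:
    """Summary statistics from a sampled call set.

    Local-ancestry CV is computed across 100 kb-window means; genome-wide CV
    across individuals.  The median tract length is supplied by the
    simulator (or a tract-calling step) since marker-level calls only bound
    it.
    """
    ind_anc = calls.individual_mean_minor()
    win = (calls.pos - 1) // window_bp
    df = pd.DataFrame({"chrom": calls.chrom, "win": win, "anc": calls.site_mean_minor()})
    local = df.groupby(["chrom", "win"], sort=False)["anc"].mean().to_numpy()
    return SummaryStats(
        float(np.nanmean(ind_anc)),
        _cv(ind_anc),
        _cv(local),
        float(tract_median_bp) if tract_median_bp is not None else np.nan,
    )


def run_reference_table(
    priors: PriorSpec,
    n_sims: int,
    sample_size: int = 69,
    seed: Optional[int] = None,
    chrom_length_bp: int = 25_000_000,
    recomb_map=None,
    site_spacing_bp: int = 25_000,
    max_N: Optional[int] = None,
    checkpoint_path=None,
    checkpoint_every: int = 500,
) -> pd.DataFrame:
    """Simulate the ABC reference table: one 25 Mb chromosome per draw.

    ``max_N`` caps the simulated population size for desk-scale runs (the
    prior value is still recorded and used for inference; the cap is a
    runtime control and documented as such).  Rows where the minor ancestry
    is absent (no tracts, e.g. p0 = 1 draws) carry NaN statistics and an
    ``ok`` flag of False; they are excluded by the fitting step.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_sims):
        draw = priors.sample(rng)
        N_sim = min(draw["N_hybrid"], max_N) if max_N else draw["N_hybrid"]
        cfg = SimConfig(
            n_chromosomes=1,
            chrom_length_bp=chrom_length_bp,
            recomb_map=recomb_map,
            N_hybrid=max(2, N_sim),
            p0=draw["p0"],
            t_admix=draw["t_admix"],
            m1=draw["m1"],
            m2=draw["m2"],
        )
        sim_seed = int(rng.integers(2**31))
        pop = simulate_hybrid_population(cfg, np.random.default_rng(sim_seed))
        row = dict(draw)
        row["seed"] = sim_seed
        try:
            med = summarize_tracts(pop, PARENT2)["median_bp"]
            sites = {
                c: np.arange(site_spacing_bp, cfg.recomb_map.chrom_length(c) + 1, site_spacing_bp)
                for c in cfg.chroms
            }
            n = min(sample_size, pop.n_individuals)
            inds = rng.choice(pop.n_individuals, size=n, replace=False)
            cs = tracts_to_calls(pop, sites, minor_parent=PARENT2, individuals=inds)
            ss = summary_stats(cs, tract_median_bp=med)
            row.update(dict(zip(STAT_NAMES, ss.as_array())))
            row["ok"] = np.isfinite(ss.as_array()).all()
        except ValueError:
            row.update({s: np.nan for s in STAT_NAMES})
            row["ok"] = False
        rows.append(row)
        if checkpoint_path and (k + 1) % checkpoint_every == 0:
            pd.DataFrame(rows).to_csv(checkpoint_path, sep="\t", index=False)
    table = pd.DataFrame(rows)
    n_bad = int((~table["ok"]).sum())
    if n_bad:
        table.attrs["n_failed"] = n_bad
    if checkpoint_path:
        table.to_csv(checkpoint_path, sep="\t", index=False)
    return table


def abc_reject_regress(
    observed: SummaryStats | np.ndarray,
    table: pd.DataFrame,
    tolerance: float = 0.005,
    priors: Optional[PriorSpec] = None,
) -> dict:
    """Rejection ABC with Epanechnikov-weighted local-linear adjustment.

    Statistics are standardized by the median absolute deviation, the
    ``ceil(tolerance * n)`` draws nearest the observed point (Euclidean) are
    accepted, and each parameter is regressed on the standardized statistics
    with Epanechnikov kernel weights; adjusted draws are the fit at the
    observed point plus residuals, truncated to the prior support.  Falls
    back to pure rejection when too few draws are accepted to fit the
    regression.
    """
    obs = observed.as_array() if isinstance(observed, SummaryStats) else np.asarray(observed, float)
    if not np.isfinite(obs).all():
        raise ValueError("observed statistics must be finite")
    tab = table[table["ok"]].reset_index(drop=True) if "ok" in table else table.reset_index(drop=True)
    S = tab[STAT_NAMES].to_numpy(dtype=float)
    n = len(tab)
    mad = stats.median_abs_deviation(S, axis=0)
    mad[mad == 0] = 1.0
    Sz = (S - np.median(S, axis=0)) / mad
    oz = (obs - np.median(S, axis=0)) / mad
    d = np.sqrt(((Sz - oz) ** 2).sum(axis=1))
    n_acc = int(np.ceil(tolerance * n))
    order = np.argsort(d)
    acc = order[:n_acc]
    delta = d[acc].max()
    if delta == 0:
        delta = 1.0
    w = 1.0 - (d[acc] / delta) ** 2
    w = np.maximum(w, 1e-12)

    out = {"accepted_index": acc, "n_accepted": n_acc, "distances": d[acc]}
    rejection = {}
    adjusted = {}
    X = np.column_stack([np.ones(n_acc), Sz[acc] - oz])
    sw = np.sqrt(w)
    underdetermined = n_acc < len(STAT_NAMES) + 2
    for name in PARAM_NAMES:
        theta = tab[name].to_numpy(dtype=float)[acc]
        rejection[name] = theta.copy()
        if underdetermined:
            adjusted[name] = theta.copy()
            continue
        y = np.log(theta) if name in LOG_PARAMS else theta
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        fitted_at_obs = beta[0]
        resid = y - X @ beta
        adj = fitted_at_obs + resid
        if name in LOG_PARAMS:
            adj = np.exp(adj)
        if priors is not None:
            lo, hi = priors.bounds(name)
            adj = np.clip(adj, lo, hi)
        adjusted[name] = adj
    if underdetermined:
        out["regression"] = "skipped: too few accepted draws"
    out["rejection"] = rejection
    out["adjusted"] = adjusted
    return out


def map_estimate(draws: np.ndarray, support: Optional[tuple[float, float]] = None, grid_size: int = 512) -> dict:
    """Posterior mode via Gaussian KDE (Silverman bandwidth) on a grid.

    Flags multimodality when a secondary peak reaches 95% of the maximum.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 50:
        raise ValueError("need at least 50 posterior draws")
    if np.ptp(draws) == 0:
        return {"map": float(draws[0]), "multimodal": False}
    lo, hi = support if support else (draws.min(), draws.max())
    grid = np.linspace(lo, hi, grid_size)
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    dens = kde(grid)
    imax = int(np.argmax(dens))
    peaks = [
        i
        for i in range(1, grid_size - 1)
        if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1] and dens[i] >= 0.95 * dens[imax]
    ]
    return {"map": float(grid[imax]), "multimodal": len(peaks) > 1, "grid": grid, "density": dens}


def coverage_validation(
    table: pd.DataFrame,
    n_test: int = 100,
    tolerance: float = 0.005,
    priors: Optional[PriorSpec] = None,
    seed=None,
) -> pd.DataFrame:
    """Self-validation: treat random table rows as pseudo-observed data and
    measure how often the true parameter falls inside the central 95% and
    50% posterior intervals."""
    rng = np.random.default_rng(seed)
    tab = table[table["ok"]].reset_index(drop=True) if "ok" in table else table.reset_index(drop=True)
    if n_test == 0:
        return pd.DataFrame(columns=["parameter", "coverage_95", "coverage_50", "n_test"])
    test_idx = rng.choice(len(tab), size=min(n_test, len(tab)), replace=False)
    hits95 = {p: 0 for p in PARAM_NAMES}
    hits50 = {p: 0 for p in PARAM_NAMES}
    for ti in test_idx:
        obs = tab.loc[ti, STAT_NAMES].to_numpy(dtype=float)
        rest = tab.drop(index=ti)
        res = abc_reject_regress(obs, rest, tolerance, priors)
        for p in PARAM_NAMES:
            draws = res["adjusted"][p]
            truth = tab.loc[ti, p]
            lo95, hi95 = np.quantile(draws, [0.025, 0.975])
            lo50, hi50 = np.quantile(draws, [0.25, 0.75])
            hits95[p] += int(lo95 <= truth <= hi95)
            hits50[p] += int(lo50 <= truth <= hi50)
    n = len(test_idx)
    return pd.DataFrame(
        {
            "parameter": PARAM_NAMES,
            "coverage_95": [hits95[p] / n for p in PARAM_NAMES],
            "coverage_50": [hits50[p] / n for p in PARAM_NAMES],
            "n_test": n,
        }
    )
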