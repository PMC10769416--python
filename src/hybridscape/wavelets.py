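"""Scale decomposition of genomic signals with the Haar wavelet transform.

Ancestry (or recombination) measured on a uniform grid is decomposed with an
orthonormal decimated Haar DWT into detail coefficients at dyadic scales.
Per-scale wavelet variances and cross-signal correlations quantify how much
of the overall Pearson correlation between two signals is carried by each
spatial scale; chromosome means contribute a separate "chrom" component and
irregular (non-dyadic) chromosome lengths leave a small "scl" remainder.

Normalization: for a chromosome whose analyzed dyadic prefix has n points,
the wavelet variance at level j is ``sum(d_j**2)/n``; these variances sum to
the population variance of the prefix (Parseval).  Scale labels are in bp:
level j captures variation at ``grid_step * 2**(j-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pywt

from .callset import AncestryCallSet

__all__ = [
    "GridSignal",
    "interpolate_signal",
    "cap_recombination",
    "dwt",
    "wavelet_correlation",
    "correlation_contributions",
    "weighted_jackknife",
]


@dataclass
class GridSignal:
    """Evenly spaced per-chromosome measurements (e.g. sample minor-parent
    ancestry averaged over individuals)."""

    step: float  # grid spacing, bp
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.chroms])


def interpolate_signal(
    calls: AncestryCallSet,
    grid_step: float = 1000.0,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> GridSignal:
    """Linear interpolation of diploid minor ancestry (dosage/2) per
    individual onto a uniform grid, then averaged across individuals.

    Grid points sit at bin centers ``(k + 1/2) * grid_step``.  Values beyond
    the outermost informative sites take the nearest site's value.
    """
    values = {}
    for c in calls.chroms:
        on_c = calls.chrom == c
        pos = calls.pos[on_c].astype(float)
        hard = calls.hard_calls[:, on_c]
        L = chrom_lengths[c] if chrom_lengths else float(pos.max())
        grid = (np.arange(int(L // grid_step)) + 0.5) * grid_step
        if grid.size == 0:
            grid = np.array([L / 2.0])
        total = np.zeros(grid.size)
        n_used = 0
        for i in range(calls.n_individuals):
            ok = hard[i] >= 0
            if not ok.any():
                continue
            p = pos[ok]
            v = hard[i, ok] / 2.0
            total += np.interp(grid, p, v)
            n_used += 1
        if n_used == 0:
            raise ValueError(f"chromosome {c} has no informative sites")
        values[c] = total / n_used
    return GridSignal(grid_step, values)


def cap_recombination(values: np.ndarray, rho_cap: float = 0.005) -> tuple[np.ndarray, float]:
    """Winsorize recombination values at ``rho_cap``; returns (capped values,
    fraction of values that hit the cap)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("recombination values must be non-negative")
    capped = np.minimum(v, rho_cap)
    return capped, float(np.mean(v > rho_cap))


# ---------------------------------------------------------------------------
# transforms

def _haar_details(x: np.ndarray) -> tuple[list[np.ndarray], int]:
    """Full-depth Haar detail coefficients of the maximal dyadic prefix.

    Returns (details by level 1..J, prefix length).  ``details[j-1]`` holds
    the level-j coefficients (scale ``step * 2**(j-1)``).
    """
    n = len(x)
    if n < 2:
        raise ValueError("signal must have at least 2 grid points")
    J = int(np.floor(np.log2(n)))
    n2 = 2**J
    coeffs = pywt.wavedec(x[:n2], "haar", level=J)
    # wavedec returns [cA_J, cD_J, ..., cD_1]; reorder to level 1..J
    details = coeffs[1:][::-1]
    return details, n2


def dwt(signal: GridSignal) -> pd.DataFrame:
    """Per-scale wavelet variances, pooled over chromosomes.

    Variance at level j is ``sum(d**2)/n`` within each chromosome's dyadic
    prefix, pooled across chromosomes weighted by prefix length; the
    variances sum to the pooled within-prefix variance (Parseval).
    """
    prod = {}  # level -> [sum d^2, n coeffs]
    n_tot = 0
    for c in signal.chroms:
        details, n2 = _haar_details(signal.values[c])
        n_tot += n2
        for j, d in enumerate(details, start=1):
            e = prod.setdefault(j, [0.0, 0])
            e[0] += float((d**2).sum())
            e[1] += d.size
    rows = [
        {
            "scale_bp": signal.step * 2 ** (j - 1),
            "level": j,
            "variance": ss / n_tot,
            "coeff_meansq": ss / n,  # flat across scales for white noise
            "n_coeffs": n,
        }
        for j, (ss, n) in sorted(prod.items())
    ]
    return pd.DataFrame(rows)


def wavelet_correlation(signalA: GridSignal, signalB: GridSignal) -> pd.DataFrame:
    """Per-scale correlation of Haar detail coefficients.

    Correlations are computed per chromosome (uncentered, as detail
    coefficients are contrasts) and averaged across chromosomes weighted by
    the number of coefficients; scales where either signal has zero variance
    on a chromosome are masked for that chromosome, not treated as zero.
    """
    if signalA.chroms != signalB.chroms or signalA.step != signalB.step:
        raise ValueError("signals must share grid and chromosomes")
    per_scale: dict[int, list[tuple[float, int]]] = {}
    for c in signalA.chroms:
        dA, n2a = _haar_details(signalA.values[c])
        dB, n2b = _haar_details(signalB.values[c])
        if n2a != n2b:
            raise ValueError("signals must have identical lengths per chromosome")
        for j, (a, b) in enumerate(zip(dA, dB), start=1):
            va, vb = float((a**2).sum()), float((b**2).sum())
            if va == 0 or vb == 0:
                continue
            r = float((a * b).sum() / np.sqrt(va * vb))
            per_scale.setdefault(j, []).append((r, a.size))
    rows = []
    for j in sorted(per_scale):
        rs = np.array([r for r, _ in per_scale[j]])
        ws = np.array([w for _, w in per_scale[j]], dtype=float)
        rows.append(
            {
                "scale_bp": signalA.step * 2 ** (j - 1),
                "level": j,
                "correlation": float((rs * ws).sum() / ws.sum()),
                "n_coeffs": int(ws.sum()),
                "n_chroms": len(rs),
            }
        )
    return pd.DataFrame(rows)


def correlation_contributions(signalA: GridSignal, signalB: GridSignal) -> pd.DataFrame:
    """Decompose the overall Pearson correlation between two concatenated
    signals into per-scale, chromosome-mean ("chrom") and leftover ("scl")
    components.

    The contribution of scale j is ``corr_j * sqrt(varA_j * varB_j) /
    sqrt(varA_total * varB_total)`` with detail products pooled across
    chromosomes; "chrom" carries the covariance of per-chromosome (prefix)
    means; "scl" is the remainder from non-dyadic chromosome tails, exactly
    zero when every chromosome length is a power of two.  Contributions sum
    to the overall Pearson correlation.
    """
    if signalA.chroms != signalB.chroms or signalA.step != signalB.step:
        raise ValueError("signals must share grid and chromosomes")
    A = signalA.concatenated()
    B = signalB.concatenated()
    n = A.size
    varA = A.var()
    varB = B.var()
    if varA == 0 or varB == 0:
        raise ValueError("zero total variance")
    denom = n * np.sqrt(varA * varB)
    r_total = float(np.corrcoef(A, B)[0, 1])

    pooled: dict[int, list[float]] = {}
    chrom_cov = 0.0
    meanA, meanB = A.mean(), B.mean()
    for c in signalA.chroms:
        a, b = signalA.values[c], signalB.values[c]
        dA, n2 = _haar_details(a)
        dB, _ = _haar_details(b)
        for j, (da, db) in enumerate(zip(dA, dB), start=1):
            e = pooled.setdefault(j, [0.0, 0.0, 0.0, 0])
            e[0] += float((da * db).sum())
            e[1] += float((da**2).sum())
            e[2] += float((db**2).sum())
            e[3] += da.size
        chrom_cov += n2 * (a[:n2].mean() - meanA) * (b[:n2].mean() - meanB)

    rows = []
    total = 0.0
    for j in sorted(pooled):
        ab, aa, bb, nc = pooled[j]
        contrib = ab / denom
        corr_j = ab / np.sqrt(aa * bb) if aa > 0 and bb > 0 else np.nan
        rows.append(
            {
                "component": f"s{j}",
                "scale_bp": signalA.step * 2 ** (j - 1),
                "correlation": corr_j,
                "variance_A": aa / n,
                "variance_B": bb / n,
                "contribution": contrib,
                "n_coeffs": nc,
            }
        )
        total += contrib
    chrom_contrib = chrom_cov / denom
    rows.append(
        {
            "component": "chrom",
            "scale_bp": np.nan,
            "correlation": np.nan,
            "variance_A": np.nan,
            "variance_B": np.nan,
            "contribution": chrom_contrib,
            "n_coeffs": len(signalA.chroms),
        }
    )
    rows.append(
        {
            "component": "scl",
            "scale_bp": np.nan,
            "correlation": np.nan,
            "variance_A": np.nan,
            "variance_B": np.nan,
            "contribution": r_total - total - chrom_contrib,
            "n_coeffs": 0,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["pearson_total"] = r_total
    return df


def weighted_jackknife(values, weights=None, conf: float = 0.95) -> dict:
    """Weighted delete-one-block jackknife for a weighted-mean statistic.

    ``values`` are per-block (per-chromosome) statistics and ``weights``
    their weights (e.g. wavelet coefficient counts).  Returns the weighted
    estimate, the bias-corrected jackknife estimate, SE, and the normal
    confidence interval.  Requires >= 3 blocks.
    """
    theta = np.asarray(values, dtype=float)
    g = theta.size
    if g < 3:
        raise ValueError("need at least 3 blocks")
    w = np.ones(g) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != theta.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per block")
    W = w.sum()
    est = float((w * theta).sum() / W)
    loo = np.array([((w * theta).sum() - w[c] * theta[c]) / (W - w[c]) for c in range(g)])
    h = W / w
    est_j = float(g * est - ((1 - w / W) * loo).sum())
    tau = h * est - (h - 1) * loo
    var = float(np.sum((tau - est_j) ** 2 / (h - 1)) / g)
    se = np.sqrt(var)
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2)
    return {
        "estimate": est,
        "jackknife_estimate": est_j,
        "se": se,
        "ci_lo": est_j - z * se,
        "ci_hi": est_j + z * se,
        "n_blocks": g,
    }
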