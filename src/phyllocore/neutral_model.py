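"""Sloan's neutral community model: fit and per-taxon partition.

The model predicts a taxon's occurrence frequency across local communities
from its mean relative abundance p in the metacommunity: with community size N
and immigration probability m, stationary relative abundances follow a
Beta(N*m*p, N*m*(1-p)) distribution, so the expected frequency of detection
above a limit d is the Beta survival function at d.  The single free parameter
m is fitted by nonlinear least squares of observed frequencies on predicted
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_prep import AbundanceTable, to_relative

__all__ = [
    "NCMFit",
    "occurrence_stats",
    "default_detection_limit",
    "predict_freq",
    "fit_ncm",
    "partition_taxa",
]


def default_detection_limit(tab: AbundanceTable) -> float:
    """Continuity-corrected detection limit: half the smallest nonzero
    within-sample relative abundance.

    Detection is the discrete event "at least one read"; matching it to the
    continuous Beta tail at half a read's relative abundance removes most of
    the discreteness bias in the fitted migration rate.
    """
    rel = to_relative(tab).values
    nonzero = rel[rel > 0]
    if nonzero.size == 0:
        raise ValueError("table has no nonzero entries")
    return float(0.5 * nonzero.min())


@dataclass
class NCMFit:
    """Fitted migration rate and fit quality of the neutral model."""

    m: float
    N: float
    Nm: float
    r2: float
    d: float
    n_taxa: int
    sse: float


def occurrence_stats(tab: AbundanceTable) -> pd.DataFrame:
    """Per-taxon mean relative abundance ``p`` and occurrence frequency ``f``.

    Taxa absent from every sample are dropped.
    """
    if tab.mode != "counts":
        raise ValueError("occurrence statistics are computed from counts")
    if tab.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rel = to_relative(tab)
    p = rel.data.mean(axis=0)
    f = (tab.data > 0).mean(axis=0)
    out = pd.DataFrame({"p": p, "f": f})
    return out[out["p"] > 0]


def predict_freq(p, m: float, N: float, d: float):
    """Expected occurrence frequency: Beta(N*m*p, N*m*(1-p)) survival at d."""
    if m <= 0:
        raise ValueError("migration rate m must be positive")
    p = np.asarray(p, dtype=float)
    return stats.beta.sf(d, N * m * p, N * m * (1.0 - p))


def fit_ncm(
    stats_df: pd.DataFrame,
    N: float,
    d: float,
    n_grid: int = 50,
) -> NCMFit:
    """Least-squares fit of m over (1e-6, 1]: coarse log grid then local refine."""
    if len(stats_df) < 10:
        raise ValueError("need at least 10 taxa to fit the neutral model")
    p = stats_df["p"].to_numpy()
    f = stats_df["f"].to_numpy()

    def sse(m: float) -> float:
        resid = f - predict_freq(p, m, N, d)
        return float(resid @ resid)

    grid = np.logspace(-6, 0, n_grid)
    losses = np.array([sse(m) for m in grid])
    best = int(np.argmin(losses))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    m_hat = float(res.x) if res.fun <= losses[best] else float(grid[best])
    final = sse(m_hat)
    if not np.isfinite(final):
        raise RuntimeError(f"neutral model fit did not converge (sse={final})")
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - final / sst if sst > 0 else np.nan
    return NCMFit(m=m_hat, N=N, Nm=N * m_hat, r2=r2, d=d, n_taxa=len(f), sse=final)


def partition_taxa(
    stats_df: pd.DataFrame,
    fit: NCMFit,
    n_samples: int,
    ci_level: float = 0.95,
) -> pd.Series:
    """Label each taxon above/within/below the Wilson band around its prediction."""
    pred = predict_freq(stats_df["p"].to_numpy(), fit.m, fit.N, fit.d)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    n = float(n_samples)
    denom = 1.0 + z**2 / n
    center = (pred + z**2 / (2 * n)) / denom
    half = z * np.sqrt(pred * (1 - pred) / n + z**2 / (4 * n**2)) / denom
    lower, upper = center - half, center + half
    f = stats_df["f"].to_numpy()
    labels = np.where(f > upper, "above", np.where(f < lower, "below", "within"))
    return pd.Series(labels, index=stats_df.index, name="partition")
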