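"""Per-sample stability indicators and core-group vs stability regressions.

AVD (average variation degree) measures how far a sample sits from the mean
community profile: the mean absolute z-score of its taxon abundances against
the per-taxon mean and standard deviation over a reference sample set.  Lower
AVD means stronger compositional convergence (higher stability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_prep import AbundanceTable
from .cohesion_network import build_network, robustness, spearman_matrix

__all__ = ["avd", "RegressionResult", "stability_regression", "robustness_replicates"]


def avd(tab, sample_set=None) -> pd.Series:
    """Per-sample average variation degree over the given sample set.

    Taxa with zero variance across the set contribute to neither the sum nor
    the divisor.  Accepts an :class:`AbundanceTable` or a plain DataFrame /
    array (the latter is useful for calibration on synthetic data).
    """
    if isinstance(tab, AbundanceTable):
        data = tab.data
    elif isinstance(tab, pd.DataFrame):
        data = tab
    else:
        data = pd.DataFrame(np.asarray(tab, dtype=float))
    if sample_set is not None:
        data = data.loc[list(sample_set)]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples to measure variation")
    x = data.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    varying = np.ptp(x, axis=0) > 0  # exact-constant taxa excluded, robust to fp rounding
    if not varying.any():
        raise ValueError("all taxa are constant across the sample set")
    z = np.abs(x[:, varying] - mu[varying]) / sd[varying]
    return pd.Series(z.mean(axis=1), index=data.index, name="avd")


@dataclass
class RegressionResult:
    """OLS slope, fit and F-test for a stability metric on group abundance."""

    slope: float
    intercept: float
    r2: float
    p: float
    n_used: int
    n_dropped: int


def stability_regression(x: pd.Series, y: pd.Series) -> RegressionResult:
    """OLS of a per-sample stability metric on group relative abundance.

    Samples with an undefined (NaN) metric are dropped and counted.
    """
    xy = pd.concat([x.rename("x"), y.rename("y")], axis=1)
    clean = xy.dropna()
    n_dropped = len(xy) - len(clean)
    if len(clean) < 5:
        raise ValueError("need at least 5 paired finite observations")
    xv = clean["x"].to_numpy()
    yv = clean["y"].to_numpy()
    if xv.std() == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(xv, yv)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n_used=len(clean),
        n_dropped=n_dropped,
    )


def robustness_replicates(
    rel_tab: AbundanceTable,
    n_boot: int = 30,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
    n_orders: int = 25,
    grid_step: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap replicates of network robustness for regression responses.

    Each replicate resamples the samples with replacement, rebuilds the
    co-occurrence network and measures robustness; the replicate's mean group
    abundance is computed by the caller from the returned sample index lists.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n = rel_tab.n_samples
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        data = rel_tab.data.iloc[idx]
        data = data.set_axis([f"b{b}_{i}" for i in range(n)], axis=0)
        boot = AbundanceTable(data, mode=rel_tab.mode)
        corr = spearman_matrix(boot)
        net = build_network(corr, r_threshold=r_threshold, p_threshold=p_threshold,
                            n_samples=n)
        if net.graph.number_of_nodes() < 2 or net.graph.number_of_edges() == 0:
            rob = 0.0
        else:
            rob = robustness(net, n_orders=n_orders, grid_step=grid_step,
                             seed=int(rng.integers(2**31 - 1))).robustness
        rows.append({"replicate": b, "sample_indices": list(map(int, idx)),
                     "robustness": rob})
    return pd.DataFrame(rows)
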