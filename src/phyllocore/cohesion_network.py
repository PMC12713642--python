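"""Cohesion, co-occurrence networks, and node-removal robustness.

Connectedness follows the null-corrected correlation approach of Herren and
McMahon: each taxon's pairwise correlations are corrected by subtracting their
expectation under a taxon-shuffle null, then averaged separately over positive
and negative corrected values.  Per-sample cohesion is the abundance-weighted
sum of connectedness, split by sign.  Networks are built from Spearman
correlations with inclusive |rho| and p thresholds, and robustness is the area
under the mean largest-component curve over random node-removal orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_prep import AbundanceTable

__all__ = [
    "ConnectednessProfile",
    "CohesionProfile",
    "CooccurrenceNetwork",
    "RobustnessResult",
    "spearman_matrix",
    "connectedness",
    "cohesion",
    "build_network",
    "robustness",
    "association_strength",
]


@dataclass
class ConnectednessProfile:
    """Per-taxon mean positive / negative null-corrected correlation."""

    positive: pd.Series  # >= 0
    negative: pd.Series  # <= 0
    null_reps: int
    seed: int
    excluded: list  # constant taxa with undefined correlations


@dataclass
class CohesionProfile:
    """Per-sample positive (>= 0) and negative (<= 0) cohesion."""

    positive: pd.Series
    negative: pd.Series


@dataclass
class CooccurrenceNetwork:
    """Undirected co-occurrence graph with the thresholds that built it."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": u, "taxon_b": v, "rho": d["rho"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "sign"])


@dataclass
class RobustnessResult:
    """Mean largest-component curve under random removal and its AUC."""

    fractions: np.ndarray
    lcc_fraction: np.ndarray
    robustness: float
    n_orders: int
    seed: int


def spearman_matrix(tab: AbundanceTable) -> pd.DataFrame:
    """Spearman rho among taxa (average-rank ties); constant taxa become NaN."""
    if tab.n_samples < 4:
        raise ValueError("need at least 4 samples for rank correlations")
    vals = tab.values
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(vals).statistic
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:  # scipy collapses the 2-taxon case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    const = vals.std(axis=0) == 0
    rho[const, :] = np.nan  # undefined for constant taxa, diagonal included
    rho[:, const] = np.nan
    return pd.DataFrame(rho, index=tab.taxon_ids, columns=tab.taxon_ids)


def connectedness(
    tab: AbundanceTable,
    null_reps: int = 200,
    seed: int = 0,
    method: str = "pearson",
) -> ConnectednessProfile:
    """Null-corrected mean positive/negative correlation per taxon.

    The null shuffles, for each pair (i, j), taxon j's abundances across
    samples while holding taxon i fixed; the mean null correlation is
    subtracted from the observed one before averaging by sign.
    """
    if null_reps < 20:
        raise ValueError("null_reps must be at least 20")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X = tab.values.astype(float)
    keep = X.std(axis=0) > 0
    excluded = [t for t, k in zip(tab.taxon_ids, keep) if not k]
    taxa = [t for t, k in zip(tab.taxon_ids, keep) if k]
    X = X[:, keep]
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
    n, k = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    Z /= np.sqrt(n)
    corr = Z.T @ Z  # observed correlation matrix

    rng = np.random.default_rng(seed)
    null_mean = np.zeros_like(corr)
    for _ in range(null_reps):
        perm = np.argsort(rng.random((n, k)), axis=0)
        Zp = np.take_along_axis(Z, perm, axis=0)
        null_mean += Z.T @ Zp  # entry (i, j): corr(x_i, shuffled x_j)
    null_mean /= null_reps
    corrected = corr - null_mean
    np.fill_diagonal(corrected, np.nan)

    pos = np.zeros(k)
    neg = np.zeros(k)
    for i in range(k):
        row = corrected[i, :]
        row = row[~np.isnan(row)]
        p = row[row > 0]
        q = row[row < 0]
        pos[i] = p.mean() if p.size else 0.0
        neg[i] = q.mean() if q.size else 0.0
    return ConnectednessProfile(
        positive=pd.Series(pos, index=taxa, name="positive_connectedness"),
        negative=pd.Series(neg, index=taxa, name="negative_connectedness"),
        null_reps=null_reps,
        seed=seed,
        excluded=excluded,
    )


def cohesion(tab: AbundanceTable, conn: ConnectednessProfile) -> CohesionProfile:
    """Per-sample abundance-weighted sum of connectedness, split by sign."""
    rel = tab.data[conn.positive.index]
    pos = rel.to_numpy() @ conn.positive.to_numpy()
    neg = rel.to_numpy() @ conn.negative.to_numpy()
    return CohesionProfile(
        positive=pd.Series(pos, index=tab.data.index, name="positive_cohesion"),
        negative=pd.Series(neg, index=tab.data.index, name="negative_cohesion"),
    )


def build_network(
    corr: pd.DataFrame,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
    n_samples: int = 0,
) -> CooccurrenceNetwork:
    """Keep edges with |rho| >= r_threshold (inclusive) and t-test p <= p_threshold."""
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    if n_samples < 4:
        raise ValueError("need at least 4 samples for edge p-values")
    g = nx.Graph()
    g.add_nodes_from(corr.index)
    rho = corr.to_numpy()
    taxa = list(corr.index)
    dof = n_samples - 2
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = rho[i, j]
            if np.isnan(r) or abs(r) < r_threshold:
                continue
            r_ = min(abs(r), 1.0 - 1e-15)
            t = r_ * np.sqrt(dof / (1.0 - r_**2))
            p = 2 * stats.t.sf(t, dof)
            if p <= p_threshold:
                g.add_edge(taxa[i], taxa[j], rho=float(r), sign="+" if r > 0 else "-")
    return CooccurrenceNetwork(graph=g, r_threshold=r_threshold, p_threshold=p_threshold)


def robustness(
    net: CooccurrenceNetwork | nx.Graph,
    n_orders: int = 100,
    grid_step: float = 0.05,
    seed: int = 0,
) -> RobustnessResult:
    """AUC of the mean largest-connected-component fraction under random removal."""
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    nodes = list(g.nodes)
    n = len(nodes)
    fractions = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    if n == 0:
        warnings.warn("empty network; robustness is 0", stacklevel=2)
        return RobustnessResult(fractions, np.zeros_like(fractions), 0.0, n_orders, seed)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_orders, len(fractions)))
    for o in range(n_orders):
        order = rng.permutation(nodes)
        for gi, f in enumerate(fractions):
            r = int(round(f * n))
            remaining = g.subgraph(order[r:])
            if remaining.number_of_nodes() == 0:
                curves[o, gi] = 0.0
            else:
                lcc = max(len(c) for c in nx.connected_components(remaining))
                curves[o, gi] = lcc / n
    mean_curve = curves.mean(axis=0)
    auc = float(np.trapezoid(mean_curve, fractions))
    return RobustnessResult(fractions, mean_curve, auc, n_orders, seed)


def association_strength(coh: CohesionProfile) -> pd.Series:
    """Positive cohesion / |negative cohesion|; NaN flags undefined samples."""
    neg = coh.negative.to_numpy()
    pos = coh.positive.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(neg != 0, pos / np.abs(neg), np.nan)
    return pd.Series(ratio, index=coh.positive.index, name="association_strength")
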