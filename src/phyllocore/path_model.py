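"""Piecewise path models with a d-separation test of overall fit.

A path model is a DAG over observed variables.  Each endogenous variable is
fitted by its own ordinary least-squares regression on its parents.  Overall
model fit is evaluated through the d-separation basis set: every non-adjacent
variable pair yields an independence claim, tested as a partial regression
t-test; Fisher's C = -2 * sum(ln p_i) follows a chi-square distribution with
2k degrees of freedom when the model is correctly specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PathModelSpec", "IndependenceClaim", "PathFit", "basis_set", "fit_paths", "evaluate_fit"]


@dataclass(frozen=True)
class IndependenceClaim:
    """Claim that ``x`` is independent of ``y`` given ``conditioning``."""

    x: str
    y: str
    conditioning: tuple


@dataclass
class PathModelSpec:
    """Directed acyclic graph of named observables."""

    edges: list

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if tuple(e) in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(tuple(e))
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model graph contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for u, v in self.edges:
            g.add_edge(u, v)
        return g

    @property
    def variables(self) -> list:
        return list(nx.topological_sort(self.graph()))

    @classmethod
    def read(cls, path) -> "PathModelSpec":
        """Read an edge-list text file with one `from<TAB>to` pair per line."""
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                u, v = line.split("\t")
                edges.append((u, v))
        return cls(edges)


@dataclass
class PathFit:
    """Fitted path model: per-edge coefficients, R2s and the Fisher's C test."""

    coefficients: pd.DataFrame  # columns: from, to, coef, std_coef, se, p
    r2: dict
    claims: pd.DataFrame  # columns: x, y, conditioning, p
    fisher_c: float
    df: int
    p: float


def basis_set(spec: PathModelSpec) -> list:
    """Enumerate the independence claims implied by the missing edges.

    For each non-adjacent pair the later variable in topological order is
    treated as the response; the conditioning set is the union of both
    variables' parents.
    """
    g = spec.graph()
    order = {v: i for i, v in enumerate(nx.topological_sort(g))}
    claims = []
    nodes = sorted(g.nodes, key=order.get)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if g.has_edge(u, v) or g.has_edge(v, u):
                continue
            cond = (set(g.predecessors(u)) | set(g.predecessors(v))) - {u, v}
            claims.append(IndependenceClaim(u, v, tuple(sorted(cond))))
    return claims


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with intercept; returns (beta, se, t-p-values, r2)."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    resid = y - Xd @ beta
    dof = n - Xd.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the number of parents")
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / sst if sst > 0 else 0.0
    return beta, se, pvals, r2


def fit_paths(spec: PathModelSpec, data: pd.DataFrame) -> PathFit:
    """Fit every component regression and compute Fisher's C over the basis set."""
    g = spec.graph()
    missing = [v for v in g.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"variables absent from data: {missing}")

    rows = []
    r2 = {}
    for v in g.nodes:
        parents = sorted(g.predecessors(v))
        if not parents:
            continue
        y = data[v].to_numpy(dtype=float)
        X = data[parents].to_numpy(dtype=float)
        try:
            beta, se, pvals, rr = _ols(y, X)
        except np.linalg.LinAlgError:
            raise ValueError(f"singular design for endogenous variable {v!r}")
        r2[v] = rr
        sy = y.std(ddof=1)
        for j, u in enumerate(parents):
            sx = data[u].std(ddof=1)
            rows.append(
                {
                    "from": u,
                    "to": v,
                    "coef": beta[j + 1],
                    "std_coef": beta[j + 1] * sx / sy if sy > 0 else np.nan,
                    "se": se[j + 1],
                    "p": pvals[j + 1],
                }
            )
    coef = pd.DataFrame(rows, columns=["from", "to", "coef", "std_coef", "se", "p"])

    claim_rows = []
    for claim in basis_set(spec):
        # response = claim.y (later variable); test partial coefficient of x
        predictors = [claim.x] + [c for c in claim.conditioning]
        y = data[claim.y].to_numpy(dtype=float)
        X = data[predictors].to_numpy(dtype=float)
        _, _, pvals, _ = _ols(y, X)
        claim_rows.append(
            {
                "x": claim.x,
                "y": claim.y,
                "conditioning": ",".join(claim.conditioning),
                "p": pvals[1],
            }
        )
    claims = pd.DataFrame(claim_rows, columns=["x", "y", "conditioning", "p"])

    k = len(claims)
    if k == 0:
        fisher_c, df, p = 0.0, 0, 1.0
    else:
        pclip = np.clip(claims["p"].to_numpy(), 1e-300, 1.0)
        fisher_c = float(-2.0 * np.log(pclip).sum())
        df = 2 * k
        p = float(stats.chi2.sf(fisher_c, df))
    return PathFit(coefficients=coef, r2=r2, claims=claims, fisher_c=fisher_c, df=df, p=p)


def evaluate_fit(fit: PathFit, alpha: float = 0.05, c_df_max: float = 2.0) -> bool:
    """Accept the model iff saturated (df=0) or C/df <= 2 and p > alpha."""
    if fit.df == 0:
        return True
    return (fit.fisher_c / fit.df) <= c_df_max and fit.p > alpha
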