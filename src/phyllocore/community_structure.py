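"""Distance-based community structure statistics.

Bray-Curtis dissimilarities, nonmetric multidimensional scaling (Kruskal
stress-1 minimised by SMACOF iterations with monotone regression), PERMANOVA
with permutation p-values, beta-dispersion and centroid distances in a
principal-coordinate embedding (negative eigenvalues handled by the imaginary
correction), and the Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .io_prep import AbundanceTable

__all__ = [
    "bray_curtis",
    "OrdinationResult",
    "nmds",
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
    "beta_dispersion",
    "centroid_distance",
    "mantel",
]


def bray_curtis(tab: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/sum(total) per sample pair."""
    vals = tab.values.astype(float)
    zero_rows = np.where(vals.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        ids = [tab.sample_ids[i] for i in zero_rows]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {ids}")
    d = squareform(pdist(vals, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in tab.sample_ids])


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class OrdinationResult:
    """NMDS configuration (centered), Kruskal stress-1, and run diagnostics."""

    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    seed: int
    converged: bool
    stress_sequence: np.ndarray  # best run; non-increasing


def _stress1(disp: np.ndarray, dist: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((disp - dist) ** 2).sum() / denom))


def _pairwise(coords: np.ndarray) -> np.ndarray:
    return pdist(coords)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Kruskal nonmetric MDS: best of seeded restarts (PCoA start + random).

    Each iteration alternates monotone regression of distances on
    dissimilarity ranks (primary ties averaged) with a Guttman update of the
    configuration.  The recorded stress sequence is non-increasing: a step
    that would increase stress terminates the run on the previous state.
    """
    D = d.data
    n = D.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k}-dimensional NMDS")
    dvec = squareform(D)
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    rng = np.random.default_rng(seed)

    def run(start: np.ndarray):
        X = start.copy()
        dist = _pairwise(X)
        seq = []
        stress_prev = np.inf
        for _ in range(max_iter):
            # isotonic regression on the dissimilarities themselves pools tied
            # values, averaging their fitted disparities
            disp = iso.fit_transform(dvec[order], dist[order])
            dhat = np.empty_like(dvec)
            dhat[order] = disp
            stress = _stress1(dhat, dist)
            if stress > stress_prev + 1e-15:
                break
            seq.append(stress)
            if stress_prev - stress < tol:
                stress_prev = stress
                break
            stress_prev = stress
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
            dist = _pairwise(X)
        return stress_prev, X, np.array(seq)

    starts = [_pcoa_coords(D, k)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.normal(size=(n, k)))
    best = None
    for start in starts:
        stress, X, seq = run(start)
        if best is None or stress < best[0]:
            best = (stress, X, seq)
    stress, X, seq = best
    X = X - X.mean(axis=0)
    coords = pd.DataFrame(X, index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coords, float(stress), n_restarts, seed, np.isfinite(stress), seq)


# ---------------------------------------------------------------------------
# principal-coordinate embedding shared by PERMANOVA-adjacent statistics


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    J = np.eye(len(A)) - np.ones_like(A) / len(A)
    return J @ A @ J


def _pcoa_coords(D: np.ndarray, k: int) -> np.ndarray:
    G = _gower_center(D)
    w, v = np.linalg.eigh(G)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(w)


def _dual_embedding(D: np.ndarray):
    """Real and imaginary coordinate blocks from the Gower eigendecomposition."""
    G = _gower_center(D)
    w, v = np.linalg.eigh(G)
    tol = 1e-10 * max(abs(w).max(), 1.0)
    pos = w > tol
    neg = w < -tol
    real = v[:, pos] * np.sqrt(w[pos])
    imag = v[:, neg] * np.sqrt(-w[neg])
    return real, imag


@dataclass
class PermanovaResult:
    """Pseudo-F, effect size R2 and permutation p for a grouping factor."""

    pseudo_f: float
    r2: float
    p: float
    n_perms: int
    groups: tuple


def _permanova_f(G: np.ndarray, labels: np.ndarray):
    """Pseudo-F and R2 from the Gower-centered inner-product matrix."""
    n = len(labels)
    levels, inverse = np.unique(labels, return_inverse=True)
    a = len(levels)
    H = np.zeros((n, n))
    for g in range(a):
        members = np.where(inverse == g)[0]
        H[np.ix_(members, members)] = 1.0 / len(members)
    ss_total = np.trace(G)
    ss_between = float(np.sum(H * G))  # trace(H G) for symmetric H
    ss_within = ss_total - ss_between
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    d: DistanceMatrix,
    groups,
    n_perms: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA; p = (#{F_perm >= F_obs} + 1) / (n_perms + 1)."""
    labels = np.asarray(groups)
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = levels[counts < 2].tolist()
        raise ValueError(f"groups with a single sample: {bad}")
    G = _gower_center(d.data)
    f_obs, r2 = _permanova_f(G, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perms):
        f_perm, _ = _permanova_f(G, labels[rng.permutation(len(labels))])
        if f_perm >= f_obs:
            count += 1
    p = (count + 1) / (n_perms + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perms, tuple(levels))


def pairwise_permanova(
    d: DistanceMatrix,
    groups,
    n_perms: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Each group pair tested separately; Holm adjustment over the family."""
    labels = pd.Series(np.asarray(groups), index=list(d.ids))
    levels = sorted(labels.unique())
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            ids = labels.index[labels.isin([a, b])].tolist()
            sub = d.filter(ids)
            res = permanova(sub, labels.loc[ids].to_numpy(), n_perms=n_perms,
                            seed=int(rng.integers(2**31 - 1)))
            rows.append({"pair": f"{a}-{b}", "pseudo_f": res.pseudo_f, "r2": res.r2,
                         "p": res.p})
    out = pd.DataFrame(rows)
    ps = out["p"].to_numpy()
    order = np.argsort(ps)
    adj = np.empty_like(ps)
    running = 0.0
    for rank, oi in enumerate(order):
        running = max(running, (len(ps) - rank) * ps[oi])
        adj[oi] = min(1.0, running)
    out["p_adj"] = adj
    return out


def beta_dispersion(d: DistanceMatrix, groups):
    """Per-sample distance to own-group centroid in the dual PCoA embedding.

    Returns (per-group mean Series, per-sample Series).  Squared distances are
    real-part minus imaginary-part contributions, clipped at zero.
    """
    labels = pd.Series(np.asarray(groups), index=list(d.ids))
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"groups need >= 2 samples: {counts[counts < 2].index.tolist()}")
    real, imag = _dual_embedding(d.data)
    dist = pd.Series(0.0, index=labels.index, name="dist_to_centroid")
    for g in labels.unique():
        members = np.where(labels.to_numpy() == g)[0]
        cr = real[members].mean(axis=0)
        ci = imag[members].mean(axis=0) if imag.size else np.zeros(0)
        d2r = ((real[members] - cr) ** 2).sum(axis=1)
        d2i = ((imag[members] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        dist.iloc[members] = np.sqrt(np.clip(d2r - d2i, 0, None))
    disp = dist.groupby(labels).mean().rename("dispersion")
    return disp, dist


def centroid_distance(d: DistanceMatrix, groups, pair) -> float:
    """Euclidean distance between two group centroids in the dual embedding."""
    labels = np.asarray(groups)
    a, b = pair
    real, imag = _dual_embedding(d.data)
    ia = np.where(labels == a)[0]
    ib = np.where(labels == b)[0]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"empty group in pair {pair}")
    d2 = ((real[ia].mean(axis=0) - real[ib].mean(axis=0)) ** 2).sum()
    if imag.size:
        d2 -= ((imag[ia].mean(axis=0) - imag[ib].mean(axis=0)) ** 2).sum()
    return float(np.sqrt(max(d2, 0.0)))


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perms: int = 999, seed: int = 0):
    """Mantel r (Pearson on lower triangles) with a one-sided permutation p."""
    if tuple(d1.ids) != tuple(d2.ids):
        raise ValueError("distance matrices must share the same samples in the same order")
    x = squareform(d1.data)
    D2 = d2.data
    y = squareform(D2)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = D2.shape[0]
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        yp = squareform(D2[np.ix_(perm, perm)])
        if np.corrcoef(x, yp)[0, 1] >= r_obs:
            count += 1
    p = (count + 1) / (n_perms + 1)
    return r_obs, float(p)
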