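"""Core microbiome detection and SU / ES / EC stratification.

A taxon is *core* when it reaches both a mean relative abundance and a
prevalence threshold across host (sphagnum) samples (defaults 0.1% and 80%,
inclusive).  Core taxa are then stratified by habitat distribution:

* ``SU``  host-unique: zero counts in every non-host sample;
* ``ES``  enriched in the host: both host-vs-litter and host-vs-soil
  zero-inflated beta contrasts significant with the higher mean in the host;
* ``EC``  environmental core: present in all three habitats, not enriched;
* ``core-unresolved``  present in exactly two habitats and not enriched.

The differential test is a two-part zero-inflated beta regression fitted by
maximum likelihood: a per-group Bernoulli zero mass and a Beta(mu*phi,
(1-mu)*phi) density for positive values, with group-specific logit(pi) and
logit(mu) and a shared precision phi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_prep import HABITATS, AbundanceTable, SampleMetadata, to_relative

__all__ = [
    "HabitatOverlap",
    "ZIBFit",
    "CoreClassification",
    "habitat_overlap",
    "detect_core",
    "fit_zib",
    "zib_contrasts",
    "classify_core",
    "group_abundance",
    "core_shares",
]


@dataclass
class HabitatOverlap:
    """Per-taxon habitat-presence category (one, two, or all three habitats)."""

    categories: pd.Series

    def proportions(self) -> pd.Series:
        return self.categories.value_counts(normalize=True)


@dataclass
class ZIBFit:
    """ML estimates of the two-part zero-inflated beta model."""

    groups: list
    pi: pd.Series  # per-group zero-inflation probability
    mu: pd.Series  # per-group beta mean
    phi: float
    loglik: float
    params: np.ndarray  # (logit_pi_g..., logit_mu_g..., log_phi)
    cov: np.ndarray | None  # covariance of params; None when degenerate
    degenerate_groups: list  # groups with no positive observations


@dataclass
class CoreClassification:
    """Per-taxon core flags, SU/ES/EC labels, and the evidence behind them."""

    table: pd.DataFrame  # index taxon; columns: is_core, label, prevalence_host,
    # mean_ra_host, p_host_vs_litter, p_host_vs_soil

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def habitat_overlap(tab: AbundanceTable, meta: SampleMetadata) -> HabitatOverlap:
    """Categorise each taxon by the set of habitats where it occurs at all."""
    present_by_hab = {}
    for hab in HABITATS:
        samples = meta.samples_in(hab)
        present_by_hab[hab] = (tab.data.loc[samples] > 0).any(axis=0)
    if not all(len(meta.samples_in(h)) > 0 for h in HABITATS):
        raise ValueError("all three habitats must be present in the metadata")
    cats = {}
    dropped = []
    for taxon in tab.taxon_ids:
        habs = tuple(sorted(h for h in HABITATS if present_by_hab[h][taxon]))
        if not habs:
            dropped.append(taxon)
            continue
        cats[taxon] = "all three" if len(habs) == 3 else "+".join(habs)
    if dropped:
        warnings.warn(f"taxa absent from every sample excluded: {dropped}", stacklevel=2)
    return HabitatOverlap(pd.Series(cats, name="habitat_overlap"))


def detect_core(
    tab: AbundanceTable,
    meta: SampleMetadata,
    host: str = "sphagnum",
    min_ra: float = 0.001,
    min_prev: float = 0.8,
) -> pd.Series:
    """Core flags: mean host relative abundance >= min_ra AND prevalence >= min_prev."""
    host_samples = meta.samples_in(host)
    if len(host_samples) < 5:
        raise ValueError(f"host habitat {host!r} has fewer than 5 samples")
    counts = tab if tab.mode == "counts" else None
    if counts is None:
        raise ValueError("detect_core expects a counts table")
    rel = to_relative(tab)
    mean_ra = rel.data.loc[host_samples].mean(axis=0)
    prev = (tab.data.loc[host_samples] > 0).mean(axis=0)
    return ((mean_ra >= min_ra) & (prev >= min_prev)).rename("is_core")


def _beta_nll(theta: np.ndarray, y: np.ndarray, gidx: np.ndarray, n_groups: int) -> float:
    """Negative log-likelihood of the beta part on positive observations."""
    logit_mu = theta[:n_groups][gidx]
    phi = np.exp(np.clip(theta[-1], -20, 20))
    mu = special.expit(np.clip(logit_mu, -30, 30))
    a = mu * phi
    b = (1 - mu) * phi
    return -float(stats.beta.logpdf(y, a, b).sum())


def _num_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    return H


def fit_zib(y, groups, squeeze: bool = True) -> ZIBFit:
    """Maximum-likelihood zero-inflated beta fit with group-specific pi and mu.

    The likelihood separates: the zero mass gives pi_g = fraction of zeros in
    group g in closed form, and the beta part is fitted by ML on the positive
    observations only (params = logit mu per group plus a shared log phi).
    ``y`` holds relative abundances in [0, 1]; values equal to 1 are squeezed
    to (n - 0.5)/n.  Groups with no positive observations get pi pinned at 1
    and no beta mean (flagged in ``degenerate_groups``).
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if any((groups == g).sum() < 3 for g in levels):
        raise ValueError("need at least 3 samples per group")
    if (y < 0).any() or (y > 1).any():
        raise ValueError("y must lie in [0, 1]")
    if squeeze and (y == 1).any():
        y = np.where(y == 1, (len(y) - 0.5) / len(y), y)
    gidx = np.searchsorted(levels, groups)
    n_groups = len(levels)

    zero = y == 0
    pi_hat = np.array([zero[gidx == i].mean() for i in range(n_groups)])
    ll_zero = 0.0
    for i in range(n_groups):
        n0 = int(zero[gidx == i].sum())
        n1 = int((~zero)[gidx == i].sum())
        if n0:
            ll_zero += n0 * np.log(pi_hat[i])
        if n1:
            ll_zero += n1 * np.log(1 - pi_hat[i])

    degenerate = [g for i, g in enumerate(levels) if pi_hat[i] == 1.0]
    pi = pd.Series(pi_hat, index=levels)
    if len(degenerate) == n_groups:
        mu = pd.Series(np.nan, index=levels)
        return ZIBFit(levels, pi, mu, np.nan, float(ll_zero), np.array([]), None, degenerate)

    ypos = y[~zero]
    gpos = gidx[~zero]
    theta0 = np.zeros(n_groups + 1)
    for i in range(n_groups):
        sub = ypos[gpos == i]
        m0 = np.clip(sub.mean() if sub.size else 0.5, 1e-4, 1 - 1e-4)
        theta0[i] = special.logit(m0)
    theta0[-1] = np.log(10.0)

    res = optimize.minimize(
        _beta_nll,
        theta0,
        args=(ypos, gpos, n_groups),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"zero-inflated beta fit failed (gradient norm n/a): {res.message}")
    theta = res.x
    mu = pd.Series(special.expit(theta[:n_groups]), index=levels)
    for g in degenerate:
        mu[g] = np.nan
    phi = float(np.exp(theta[-1]))
    H = _num_hessian(lambda t: _beta_nll(t, ypos, gpos, n_groups), theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    loglik = float(ll_zero - res.fun)
    return ZIBFit(levels, pi, mu, phi, loglik, theta, cov, degenerate)


def zib_contrasts(fit: ZIBFit, host: str, others: list, adjust: str = "mvn") -> pd.DataFrame:
    """Wald tests of logit(mu_host) - logit(mu_other) for each other group.

    ``adjust='mvn'`` applies the single-step multivariate-normal (Tukey-style)
    familywise adjustment over the contrast family; ``'holm'`` is the fallback.
    """
    n_groups = len(fit.groups)
    idx = {g: i for i, g in enumerate(fit.groups)}

    def _contrast_vec(other):
        L = np.zeros(n_groups + 1)
        L[idx[host]] = 1.0
        L[idx[other]] = -1.0
        return L

    rows = []
    zvals, keep = [], []
    for other in others:
        if other in fit.degenerate_groups or host in fit.degenerate_groups or fit.cov is None:
            rows.append({"contrast": f"{host}-{other}", "estimate": np.nan, "z": np.nan,
                         "p_raw": np.nan})
            continue
        L = _contrast_vec(other)
        est = float(L @ fit.params)
        var = float(L @ fit.cov @ L)
        z = est / np.sqrt(var) if var > 0 else np.nan
        rows.append({"contrast": f"{host}-{other}", "estimate": est, "z": z,
                     "p_raw": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan})
        zvals.append(z)
        keep.append(len(rows) - 1)
    out = pd.DataFrame(rows)
    out["p_adj"] = out["p_raw"]
    if len(keep) >= 2:
        if adjust == "mvn":
            # correlation of the two contrasts under the fitted covariance
            Ls = [
                _contrast_vec(other)
                for other in others
                if f"{host}-{other}" in out.loc[keep, "contrast"].values
            ]
            C = np.array([[float(a @ fit.cov @ b) for b in Ls] for a in Ls])
            sd = np.sqrt(np.diag(C))
            R = C / np.outer(sd, sd)
            for row_i, z in zip(keep, zvals):
                if not np.isfinite(z):
                    continue
                a = abs(z)
                inside = stats.multivariate_normal(mean=np.zeros(len(Ls)), cov=R).cdf(
                    np.full(len(Ls), a), lower_limit=np.full(len(Ls), -a)
                )
                out.loc[row_i, "p_adj"] = min(1.0, 1.0 - float(inside))
        elif adjust == "holm":
            ps = out.loc[keep, "p_raw"].to_numpy()
            order = np.argsort(ps)
            adj = np.empty_like(ps)
            running = 0.0
            for rank, oi in enumerate(order):
                running = max(running, (len(ps) - rank) * ps[oi])
                adj[oi] = min(1.0, running)
            out.loc[keep, "p_adj"] = adj
    return out


def classify_core(
    tab: AbundanceTable,
    meta: SampleMetadata,
    core_flags: pd.Series,
    host: str = "sphagnum",
    alpha: float = 0.05,
) -> CoreClassification:
    """Stratify core taxa into SU / ES / EC / core-unresolved."""
    rel = to_relative(tab)
    host_samples = meta.samples_in(host)
    others = [h for h in HABITATS if h != host]
    habitat = meta.data["habitat"]
    rows = {}
    for taxon in tab.taxon_ids:
        counts = tab.data[taxon]
        entry = {
            "is_core": bool(core_flags.get(taxon, False)),
            "label": "non-core",
            "prevalence_host": float((counts.loc[host_samples] > 0).mean()),
            "mean_ra_host": float(rel.data[taxon].loc[host_samples].mean()),
            "p_host_vs_litter": np.nan,
            "p_host_vs_soil": np.nan,
        }
        if not entry["is_core"]:
            rows[taxon] = entry
            continue
        nonhost = counts.loc[habitat != host]
        if (nonhost == 0).all():
            entry["label"] = "SU"
            rows[taxon] = entry
            continue
        fit = fit_zib(rel.data[taxon].to_numpy(), habitat.to_numpy())
        contrasts = zib_contrasts(fit, host, others)
        pmap = dict(zip(contrasts["contrast"], contrasts["p_adj"]))
        entry["p_host_vs_litter"] = pmap.get(f"{host}-litter", np.nan)
        entry["p_host_vs_soil"] = pmap.get(f"{host}-soil", np.nan)
        mu = fit.mu
        enriched = (
            np.isfinite(entry["p_host_vs_litter"])
            and np.isfinite(entry["p_host_vs_soil"])
            and entry["p_host_vs_litter"] < alpha
            and entry["p_host_vs_soil"] < alpha
            and all(mu[host] > mu[o] for o in others if np.isfinite(mu[o]))
        )
        present_all = all((counts.loc[meta.samples_in(h)] > 0).any() for h in HABITATS)
        if enriched:
            entry["label"] = "ES"
        elif present_all:
            entry["label"] = "EC"
        else:
            entry["label"] = "core-unresolved"
        rows[taxon] = entry
    table = pd.DataFrame.from_dict(rows, orient="index")
    return CoreClassification(table)


def group_abundance(
    tab: AbundanceTable,
    classification: CoreClassification,
    grouping: str,
) -> pd.Series:
    """Per-sample summed relative abundance of a core group.

    ``grouping`` is one of ``total-core``, ``SU+ES``, ``EC``.
    """
    labels = classification.labels
    if grouping == "total-core":
        members = labels.index[classification.table["is_core"]]
    elif grouping == "SU+ES":
        members = labels.index[labels.isin(["SU", "ES"])]
    elif grouping == "EC":
        members = labels.index[labels == "EC"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rel = to_relative(tab) if tab.mode == "counts" else tab
    if len(members) == 0:
        return pd.Series(0.0, index=rel.data.index, name=grouping)
    return rel.data[list(members)].sum(axis=1).rename(grouping)


def core_shares(tab: AbundanceTable, classification: CoreClassification) -> pd.DataFrame:
    """Share of core ASV count and of summed core abundance per group."""
    labels = classification.labels
    core = classification.table["is_core"]
    core_taxa = labels.index[core]
    rel = to_relative(tab) if tab.mode == "counts" else tab
    total_ab = rel.data[list(core_taxa)].mean(axis=0).sum()
    rows = {}
    for name, members in {
        "SU+ES": labels.index[labels.isin(["SU", "ES"])],
        "EC": labels.index[labels == "EC"],
        "core-unresolved": labels.index[labels == "core-unresolved"],
    }.items():
        ab = rel.data[list(members)].mean(axis=0).sum() if len(members) else 0.0
        rows[name] = {
            "count_share": len(members) / len(core_taxa) if len(core_taxa) else 0.0,
            "abundance_share": ab / total_ab if total_ab > 0 else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
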