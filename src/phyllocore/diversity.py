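"""Alpha diversity, phylogenetic structure, and habitat-effect testing.

Faith's PD follows the rooted convention (the path to the root is included,
which matters for single-tip communities).  NRI is the negative standardized
effect size of the unweighted mean pairwise patristic distance (MPD) against a
tip-label-shuffle null; positive NRI means phylogenetic clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io_prep import AbundanceTable, SampleMetadata

__all__ = [
    "richness",
    "inverse_simpson",
    "faith_pd",
    "patristic_distances",
    "nri",
    "diversity_profile",
    "HabitatEffectReport",
    "habitat_effect_test",
]


def richness(sample) -> int:
    """Number of taxa with abundance > 0."""
    return int((np.asarray(sample, dtype=float) > 0).sum())


def inverse_simpson(sample) -> float:
    """1 / sum(p_i^2) over within-sample relative abundances."""
    x = np.asarray(sample, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    p = x / total
    return float(1.0 / (p**2).sum())


def faith_pd(sample, taxon_ids, tree) -> float:
    """Total branch length of the minimal rooted subtree spanning present taxa."""
    x = np.asarray(sample, dtype=float)
    present = [t for t, v in zip(taxon_ids, x) if v > 0]
    if not present:
        return 0.0
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(present) - tips)
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")
    sheared = tree.shear(present)
    return float(sum(n.length or 0.0 for n in sheared.traverse(include_self=True)))


def patristic_distances(tree) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix as a labelled DataFrame."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def nri(
    sample,
    taxon_ids,
    tree=None,
    n_null: int = 999,
    seed: int = 0,
    dist: pd.DataFrame | None = None,
) -> float:
    """Net relatedness index from unweighted MPD with a tip-shuffle null.

    Shuffling tip labels across the whole tree is equivalent to drawing a
    uniformly random tip set of the same size, which is how the null is
    sampled.  ``dist`` may carry a precomputed patristic matrix.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    if dist is None:
        if tree is None:
            raise ValueError("provide either a tree or a precomputed distance matrix")
        dist = patristic_distances(tree)
    x = np.asarray(sample, dtype=float)
    present = [t for t, v in zip(taxon_ids, x) if v > 0]
    if len(present) < 2:
        raise ValueError("NRI needs at least 2 present taxa")
    missing = sorted(set(present) - set(dist.index))
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")
    D = dist.to_numpy()
    all_idx = np.arange(len(dist.index))
    pos = {t: i for i, t in enumerate(dist.index)}
    idx = np.array([pos[t] for t in present])
    k = len(idx)
    mpd_obs = _mpd(D, idx)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for r in range(n_null):
        null[r] = _mpd(D, rng.choice(all_idx, size=k, replace=False))
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null (zero variance); is the community all tips?")
    return float(-(mpd_obs - null.mean()) / sd)


def _mpd(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    k = len(idx)
    return sub.sum() / (k * (k - 1))


def diversity_profile(
    tab: AbundanceTable,
    tree=None,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample richness, inverse Simpson, and (with a tree) Faith PD and NRI."""
    rows = {}
    dist = patristic_distances(tree) if tree is not None else None
    rng = np.random.default_rng(seed)
    for sid in tab.sample_ids:
        x = tab.data.loc[sid].to_numpy()
        row = {"richness": richness(x), "inverse_simpson": inverse_simpson(x)}
        if tree is not None:
            row["faith_pd"] = faith_pd(x, tab.taxon_ids, tree)
            row["nri"] = nri(
                x,
                tab.taxon_ids,
                n_null=n_null,
                seed=int(rng.integers(2**31 - 1)),
                dist=dist,
            )
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class HabitatEffectReport:
    """Type II ANOVA table plus Tukey-adjusted pairwise habitat contrasts."""

    anova: pd.DataFrame
    pairwise: pd.DataFrame
    model_formula: str


def habitat_effect_test(values: pd.Series, meta: SampleMetadata) -> HabitatEffectReport:
    """Fit value ~ habitat + site (+ interaction when estimable), Type II ANOVA.

    Pairwise habitat contrasts are differences of habitat marginal means
    (averaged over sites) with familywise adjustment via the studentized range
    distribution.
    """
    df = meta.data.loc[values.index, ["habitat", "site"]].copy()
    df["value"] = values.to_numpy(dtype=float)
    counts = df.groupby("habitat").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 habitats with at least 2 samples each")

    # degenerate response: no variance at all
    if np.allclose(df["value"].to_numpy(), df["value"].iloc[0]):
        habs = sorted(df["habitat"].unique())
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0},
            index=["C(habitat)", "C(site)", "C(habitat):C(site)", "Residual"],
        )
        pairs = [(a, b) for i, a in enumerate(habs) for b in habs[i + 1 :]]
        pairwise = pd.DataFrame(
            {"pair": [f"{a}-{b}" for a, b in pairs], "estimate": 0.0, "p_adj": 1.0}
        )
        return HabitatEffectReport(anova, pairwise, "value ~ constant")

    cells = df.groupby(["habitat", "site"]).size()
    full_grid = len(df["habitat"].unique()) * len(df["site"].unique())
    with_interaction = len(cells) == full_grid and (cells > 0).all() and (cells >= 2).any()
    formula = (
        "value ~ C(habitat) + C(site) + C(habitat):C(site)"
        if with_interaction
        else "value ~ C(habitat) + C(site)"
    )
    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design for formula {formula!r} (aliased terms)")
    anova = sm.stats.anova_lm(model, typ=2)

    # habitat marginal means: average the cell design rows over sites
    design_info = model.model.data.design_info
    sites = sorted(df["site"].unique())
    habs = sorted(df["habitat"].unique())
    import patsy

    lvecs = {}
    for hab in habs:
        grid = pd.DataFrame({"habitat": hab, "site": sites})
        (mat,) = patsy.build_design_matrices([design_info], grid)
        lvecs[hab] = np.asarray(mat).mean(axis=0)
    cov = model.cov_params().to_numpy()
    dfresid = model.df_resid
    rows = []
    for i, a in enumerate(habs):
        for b in habs[i + 1 :]:
            L = lvecs[a] - lvecs[b]
            est = float(L @ model.params.to_numpy())
            se = float(np.sqrt(L @ cov @ L))
            if se == 0:
                p = 1.0
            else:
                q = abs(est) / se * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, len(habs), dfresid))
            rows.append({"pair": f"{a}-{b}", "estimate": est, "se": se, "p_adj": min(1.0, p)})
    pairwise = pd.DataFrame(rows)
    return HabitatEffectReport(anova, pairwise, formula)
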