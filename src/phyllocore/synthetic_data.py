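"""Synthetic fixtures with the statistical structure the analysis assumes.

The stratified generator emulates the field design the pipeline targets: three
vertically stacked habitats (litter, sphagnum moss, soil) sampled at 5 sites x
5 plots (75 samples), with taxa planted in known ecological classes:

* ``SU``   host-unique core taxa, structurally absent outside the host habitat;
* ``ES``   host-enriched core taxa, expected abundance ``enrichment_fold``
  higher in the host than elsewhere;
* ``EC``   environmental core taxa, habitat-independent expectation;
* habitat specialists (drive the habitat-overlap patterns) and low-abundance
  background generalists.

Counts are rounded log-normal intensities with per-class structural
zero-inflation, so the zero-inflated beta model fitted downstream is correctly
specified.  Covariate effects (pH, elevation) act multiplicatively on the
expected abundance (i.e. linearly on its log), so expectations are positive by
construction.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_prep import HABITATS, AbundanceTable, SampleMetadata
from .path_model import PathModelSpec

__all__ = [
    "StratifiedScenario",
    "GroundTruth",
    "simulate_stratified_system",
    "simulate_neutral_local_communities",
    "simulate_tree",
    "simulate_path_data",
]

_CLASSES = ("SU", "ES", "EC", "specialist", "background")


@dataclass
class StratifiedScenario:
    """Parameters of the stratified litter-moss-soil community generator.

    Defaults mirror the study design the pipeline is built for: 5 sites x
    5 plots x 3 habitats = 75 samples, 20 planted taxa in each core class.
    ``enrichment_fold`` multiplies the expected host abundance of ES taxa
    relative to the other habitats.  ``zero_inflation`` is the per-class
    probability of a structural zero in any sample where the taxon can occur.
    """

    n_sites: int = 5
    n_plots_per_site: int = 5
    host: str = "sphagnum"
    n_su: int = 20
    n_es: int = 20
    n_ec: int = 20
    n_specialist: int = 30  # split round-robin across the three habitats
    n_background: int = 60
    enrichment_fold: float = 5.0
    zero_inflation: dict = field(
        default_factory=lambda: {
            "SU": 0.05,
            "ES": 0.05,
            "EC": 0.10,
            "specialist": 0.20,
            "background": 0.40,
        }
    )
    # log-normal law for expected counts: per-class median reads and log-sd
    abundance_medians: dict = field(
        default_factory=lambda: {
            "SU": 120.0,
            "ES": 120.0,
            "EC": 120.0,
            "specialist": 60.0,
            "background": 12.0,
        }
    )
    abundance_sdlog: float = 0.6
    taxon_sdlog: float = 0.35  # between-taxon spread of the class median
    # (beta_pH, beta_elevation) on log expected abundance of each class,
    # covariates standardised; EC tracks pH, host-specific classes elevation
    covariate_effects: dict = field(
        default_factory=lambda: {
            "SU": (0.0, -0.3),
            "ES": (0.0, -0.3),
            "EC": (0.4, 0.0),
            "specialist": (0.0, 0.0),
            "background": (0.0, 0.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_plots_per_site <= 0:
            raise ValueError("site and plot counts must be positive")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        for cls, z in self.zero_inflation.items():
            if not 0 <= z <= 1:
                raise ValueError(f"zero_inflation[{cls}] outside [0, 1]")
        if self.host not in HABITATS:
            raise ValueError(f"host must be one of {HABITATS}")


@dataclass
class GroundTruth:
    """Planted labels and effects behind a synthetic scenario."""

    taxon_labels: pd.Series  # SU / ES / EC / other
    covariates: pd.DataFrame  # true pH and elevation per sample
    path_coefficients: dict  # true coefficients of the function proxy


def _sample_frame(scn: StratifiedScenario) -> pd.DataFrame:
    rows = []
    for s in range(scn.n_sites):
        site = chr(ord("A") + s)
        for p in range(scn.n_plots_per_site):
            plot = f"{site}{p + 1}"
            for hab in HABITATS:
                rows.append(
                    {"sample_id": f"{plot}_{hab}", "habitat": hab, "site": site, "plot": plot}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_stratified_system(scn: StratifiedScenario):
    """Generate (counts table, metadata, ground truth) for a scenario."""
    rng = np.random.default_rng(scn.seed)
    meta = _sample_frame(scn)
    n_samples = len(meta)

    # covariates: elevation is a site-level gradient, pH has habitat baselines
    site_codes = meta["site"].astype("category").cat.codes.to_numpy()
    elevation = 1100.0 + 100.0 * site_codes + rng.normal(0, 15.0, n_samples)
    ph_base = {"litter": 4.8, "sphagnum": 4.0, "soil": 4.4}
    ph = np.array([ph_base[h] for h in meta["habitat"]]) + rng.normal(0, 0.25, n_samples)
    ph = np.clip(ph, 2.5, 9.0)
    meta["pH"] = ph
    meta["elevation"] = elevation
    z_ph = (ph - ph.mean()) / ph.std()
    z_el = (elevation - elevation.mean()) / elevation.std()

    taxa, classes = [], []
    for cls, n in (
        ("SU", scn.n_su),
        ("ES", scn.n_es),
        ("EC", scn.n_ec),
        ("specialist", scn.n_specialist),
        ("background", scn.n_background),
    ):
        for i in range(n):
            taxa.append(f"{cls}_{i + 1:03d}")
            classes.append(cls)
    classes = np.array(classes)
    specialist_hab = {
        t: HABITATS[i % 3]
        for i, t in enumerate([t for t, c in zip(taxa, classes) if c == "specialist"])
    }

    habitats = meta["habitat"].to_numpy()
    counts = np.zeros((n_samples, len(taxa)), dtype=np.int64)
    taxon_offset = rng.normal(0.0, scn.taxon_sdlog, len(taxa))
    for j, (taxon, cls) in enumerate(zip(taxa, classes)):
        median = scn.abundance_medians[cls]
        b_ph, b_el = scn.covariate_effects.get(cls, (0.0, 0.0))
        log_mu = np.log(median) + taxon_offset[j] + b_ph * z_ph + b_el * z_el
        if cls == "SU":
            allowed = habitats == scn.host
        elif cls == "specialist":
            allowed = habitats == specialist_hab[taxon]
        else:
            allowed = np.ones(n_samples, dtype=bool)
        if cls == "ES":
            log_mu = log_mu - np.where(habitats == scn.host, 0.0, np.log(scn.enrichment_fold))
        intensity = np.exp(log_mu + rng.normal(0.0, scn.abundance_sdlog, n_samples))
        structural = rng.random(n_samples) < scn.zero_inflation[cls]
        intensity = np.where(allowed & ~structural, intensity, 0.0)
        counts[:, j] = np.rint(intensity).astype(np.int64)

    tab = AbundanceTable(pd.DataFrame(counts, index=meta.index, columns=taxa), mode="counts")

    # function proxy: pathway abundance driven by host-specific core share,
    # pH and elevation -- known coefficients for path-model checks
    rel = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
    host_core = rel[:, (classes == "SU") | (classes == "ES")].sum(axis=1)
    path_coefficients = {"host_core": -0.6, "pH": -0.35, "elevation": -0.4, "noise_sd": 0.3}
    zc = (host_core - host_core.mean()) / (host_core.std() if host_core.std() > 0 else 1.0)
    meta["pathway_carbon_energy"] = (
        path_coefficients["host_core"] * zc
        + path_coefficients["pH"] * z_ph
        + path_coefficients["elevation"] * z_el
        + rng.normal(0, path_coefficients["noise_sd"], n_samples)
    )

    labels = pd.Series(
        np.where(np.isin(classes, ("SU", "ES", "EC")), classes, "other"), index=taxa, name="label"
    )
    truth = GroundTruth(
        taxon_labels=labels,
        covariates=meta[["pH", "elevation"]].copy(),
        path_coefficients=path_coefficients,
    )
    return tab, SampleMetadata(meta), truth


def simulate_neutral_local_communities(
    source_pool: np.ndarray,
    n_communities: int,
    community_size: int,
    migration_m: float,
    generations: int,
    seed: int,
) -> AbundanceTable:
    """Individual-based neutral assembly of local communities.

    Each generation one randomly chosen individual dies; with probability
    ``migration_m`` its replacement is drawn from the source pool, otherwise it
    is a copy of a randomly chosen local individual.  Communities start as
    random samples from the pool, so after a few multiples of
    ``community_size / migration_m`` events abundances follow the stationary
    distribution the neutral community model assumes.
    """
    source_pool = np.asarray(source_pool, dtype=float)
    if community_size <= 0:
        raise ValueError("community_size must be positive")
    if not 0 < migration_m <= 1:
        raise ValueError("migration_m must lie in (0, 1]")
    if not np.isclose(source_pool.sum(), 1.0):
        raise ValueError("source pool must sum to 1")
    rng = np.random.default_rng(seed)
    n_taxa = len(source_pool)
    cdf = np.cumsum(source_pool)
    out = np.zeros((n_communities, n_taxa), dtype=np.int64)
    for c in range(n_communities):
        comm = np.searchsorted(cdf, rng.random(community_size))
        deaths = rng.integers(community_size, size=generations)
        migrate = rng.random(generations) < migration_m
        source_draws = np.searchsorted(cdf, rng.random(generations))
        local_picks = rng.integers(community_size, size=generations)
        for t in range(generations):
            if migrate[t]:
                comm[deaths[t]] = source_draws[t]
            else:
                comm[deaths[t]] = comm[local_picks[t]]
        out[c] = np.bincount(comm, minlength=n_taxa)
    idx = [f"community_{c + 1}" for c in range(n_communities)]
    cols = [f"taxon_{j + 1}" for j in range(n_taxa)]
    return AbundanceTable(pd.DataFrame(out, index=idx, columns=cols), mode="counts")


def simulate_tree(taxon_ids, seed: int) -> TreeNode:
    """Random rooted binary (Yule-style) tree with exponential branch lengths."""
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    rng = np.random.default_rng(seed)
    nodes = []
    for t in taxon_ids:
        tip = TreeNode(name=str(t))
        tip.length = float(rng.exponential(1.0)) + 1e-6
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((i, j))
        parent = TreeNode()
        parent.length = float(rng.exponential(1.0)) + 1e-6
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def simulate_path_data(
    dag: PathModelSpec,
    n: int,
    coefficients: dict,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Linear-Gaussian data generated in topological order.

    ``coefficients`` maps each edge ``(from, to)`` to its path coefficient;
    exogenous variables are standard normal; endogenous noise has sd
    ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    g = dag.graph()
    data = {}
    for v in dag.variables:
        parents = sorted(g.predecessors(v))
        if not parents:
            data[v] = rng.normal(0.0, 1.0, n)
        else:
            x = noise_sd * rng.normal(0.0, 1.0, n)
            for u in parents:
                x = x + coefficients[(u, v)] * data[u]
            data[v] = x
    return pd.DataFrame(data)
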