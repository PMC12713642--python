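"""End-to-end pipeline: prep -> diversity -> assembly -> core -> structure ->
stability -> path models, with deterministic per-stage seeding and a manifest.

Every stochastic stage receives a seed derived from the master seed and the
stage name (SHA-256, truncated below 2**31), so identical config + inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    cohesion_network as cn,
    community_structure as cs,
    core_partition as cp,
    diversity as dv,
    io_prep as io,
    neutral_model as nm,
    path_model as pm,
    stability as st,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "stage_seed"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    counts: str
    meta: str
    outdir: str
    tree: str | None = None
    host: str = "sphagnum"
    min_reads: int = 10
    rarefy_depth: str | int = "AUTO"
    core_min_ra: float = 0.001
    core_min_prev: float = 0.8
    alpha: float = 0.05
    network_r: float = 0.6
    network_p: float = 0.05
    n_perms: int = 999
    nri_null_reps: int = 199
    cohesion_null_reps: int = 200
    nmds_restarts: int = 10
    robustness_orders: int = 100
    robustness_grid: float = 0.05
    n_boot: int = 20
    path_spec: str | None = None
    seed: int = 42

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- prep ------------------------------------------------------------
    stage = "prep"
    try:
        raw = io.read_abundance_table(cfg.counts)
        meta = io.read_sample_metadata(cfg.meta)
        meta = meta.aligned_to(raw.sample_ids)
        filtered = io.filter_rare_asvs(raw, min_total=cfg.min_reads)
        totals = filtered.data.sum(axis=1)
        depth = int(totals.min()) if cfg.rarefy_depth == "AUTO" else int(cfg.rarefy_depth)
        counts = io.rarefy(filtered, depth, seed=stage_seed(cfg.seed, stage))
        rel = io.to_relative(counts)
        io.write_abundance_table(counts, out / "counts_rarefied.tsv")
        results["prep"] = {
            "n_samples": counts.n_samples,
            "n_taxa": counts.n_taxa,
            "n_taxa_removed": raw.n_taxa - filtered.n_taxa,
            "rarefy_depth": depth,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e)

    # ---- diversity -------------------------------------------------------
    stage = "diversity"
    try:
        tree = io.read_tree(cfg.tree) if cfg.tree else None
        if tree is None:
            raise FileNotFoundError("a tree is required for PD and NRI")
        prof = dv.diversity_profile(counts, tree=tree, n_null=cfg.nri_null_reps,
                                    seed=stage_seed(cfg.seed, stage))
        _write(prof, out / "diversity_profile.tsv")
        tests = []
        for metric in prof.columns:
            rep = dv.habitat_effect_test(prof[metric], meta)
            hab = rep.anova.loc["C(habitat)"]
            tests.append({"metric": metric, "F_habitat": hab["F"], "p_habitat": hab["PR(>F)"]})
        _write(pd.DataFrame(tests).set_index("metric"), out / "diversity_tests.tsv")
        results["diversity"] = {"metrics": list(prof.columns)}
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e)

    # ---- neutral model per habitat ----------------------------------------
    stage = "ncm"
    try:
        rows = []
        for hab in io.HABITATS:
            sub = counts.subset_samples(meta.samples_in(hab))
            stats_df = nm.occurrence_stats(sub)
            d = float(0.5 / depth)  # continuity-corrected detection limit
            fit = nm.fit_ncm(stats_df, N=depth, d=d)
            part = nm.partition_taxa(stats_df, fit, n_samples=sub.n_samples)
            frac = part.value_counts(normalize=True)
            rows.append({
                "habitat": hab, "m": fit.m, "N": fit.N, "Nm": fit.Nm, "r2": fit.r2,
                "d": fit.d, "n_taxa": fit.n_taxa,
                "frac_above": float(frac.get("above", 0.0)),
                "frac_within": float(frac.get("within", 0.0)),
                "frac_below": float(frac.get("below", 0.0)),
            })
        ncm_df = pd.DataFrame(rows).set_index("habitat")
        _write(ncm_df, out / "ncm_fits.tsv")
        results["ncm"] = {"r2": ncm_df["r2"].to_dict()}
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e)

    # ---- core partition ----------------------------------------------------
    stage = "core"
    try:
        overlap = cp.habitat_overlap(counts, meta)
        core_flags = cp.detect_core(counts, meta, host=cfg.host,
                                    min_ra=cfg.core_min_ra, min_prev=cfg.core_min_prev)
        classification = cp.classify_core(counts, meta, core_flags, host=cfg.host,
                                          alpha=cfg.alpha)
        _write(classification.table, out / "core_classification.tsv")
        _write(cp.core_shares(counts, classification), out / "core_shares.tsv")
        groups_ab = pd.DataFrame({
            g: cp.group_abundance(counts, classification, g)
            for g in ("total-core", "SU+ES", "EC")
        })
        _write(groups_ab, out / "core_group_abundance.tsv")
        _write(overlap.categories.to_frame(), out / "habitat_overlap.tsv")
        results["core"] = {
            "n_core": int(core_flags.sum()),
            "labels": classification.labels[core_flags].value_counts().to_dict(),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e)

    # ---- community structure ----------------------------------------------
    stage = "structure"
    try:
        seed = stage_seed(cfg.seed, stage)
        labels = classification.labels
        subsets = {"full": list(counts.taxon_ids)}
        subsets["total-core"] = list(labels.index[classification.table["is_core"]])
        subsets["SU+ES"] = list(labels.index[labels.isin(["SU", "ES"])])
        subsets["EC"] = list(labels.index[labels == "EC"])
        habs = meta.data["habitat"].loc[counts.sample_ids].to_numpy()
        struct_rows = []
        host_dms = {}
        nmds1 = None
        for name, taxa in subsets.items():
            if len(taxa) < 2:
                warnings.warn(f"subset {name!r} too small for structure statistics")
                continue
            sub_counts = counts.subset_taxa(taxa)
            keep = sub_counts.data.sum(axis=1) > 0
            sub_counts = sub_counts.subset_samples(sub_counts.data.index[keep])
            sub_habs = habs[keep.to_numpy()]
            dm = cs.bray_curtis(io.to_relative(sub_counts))
            ord_res = cs.nmds(dm, k=2, n_restarts=cfg.nmds_restarts, seed=seed)
            if name == "full":
                nmds1 = ord_res.coordinates["NMDS1"]
                _write(ord_res.coordinates.assign(stress=ord_res.stress),
                       out / "nmds_full.tsv")
            glob = cs.permanova(dm, sub_habs, n_perms=cfg.n_perms, seed=seed)
            pw = cs.pairwise_permanova(dm, sub_habs, n_perms=cfg.n_perms, seed=seed)
            disp, _ = cs.beta_dispersion(dm, sub_habs)
            row = {"subset": name, "stress": ord_res.stress, "permanova_r2": glob.r2,
                   "permanova_p": glob.p}
            for hab in io.HABITATS:
                row[f"disp_{hab}"] = float(disp.get(hab, np.nan))
            for other in io.HABITATS:
                if other != cfg.host:
                    row[f"cdis_{cfg.host}_{other}"] = cs.centroid_distance(
                        dm, sub_habs, (cfg.host, other))
            struct_rows.append(row)
            _write(pw.set_index("pair"), out / f"permanova_pairwise_{name.replace('+','_')}.tsv")
            # host-only distance matrices for the Mantel comparison
            host_ids = [s for s, h in zip(sub_counts.sample_ids, sub_habs)
                        if h == cfg.host]
            host_sub = sub_counts.subset_samples(host_ids)
            nonzero = host_sub.data.sum(axis=1) > 0
            host_sub = host_sub.subset_samples(host_sub.data.index[nonzero])
            if host_sub.n_samples >= 4:
                host_dms[name] = cs.bray_curtis(io.to_relative(host_sub))
        mantel_rows = []
        for name in ("total-core", "SU+ES", "EC"):
            if name in host_dms and "full" in host_dms:
                common = [s for s in host_dms["full"].ids if s in host_dms[name].ids]
                r, p = cs.mantel(host_dms["full"].filter(common),
                                 host_dms[name].filter(common),
                                 n_perms=cfg.n_perms, seed=seed)
                mantel_rows.append({"subset": name, "mantel_r": r, "p": p})
        _write(pd.DataFrame(struct_rows).set_index("subset"), out / "structure_stats.tsv")
        _write(pd.DataFrame(mantel_rows).set_index("subset") if mantel_rows
               else pd.DataFrame(columns=["mantel_r", "p"]), out / "mantel_core_vs_full.tsv")
        results["structure"] = {"subsets": list(subsets)}
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e)

    # ---- stability ---------------------------------------------------------
    stage = "stability"
    try:
        seed = stage_seed(cfg.seed, stage)
        conn = cn.connectedness(rel, null_reps=cfg.cohesion_null_reps, seed=seed)
        coh = cn.cohesion(rel, conn)
        assoc = cn.association_strength(coh)
        avd_all = []
        for hab in io.HABITATS:
            ids = meta.samples_in(hab)
            avd_all.append(st.avd(rel.data, sample_set=ids))
        avd_series = pd.concat(avd_all).loc[rel.data.index]
        stability_df = pd.DataFrame({
            "avd": avd_series,
            "positive_cohesion": coh.positive,
            "negative_cohesion": coh.negative,
            "association_strength": assoc,
        })
        _write(stability_df, out / "stability_profile.tsv")

        host_ids = meta.samples_in(cfg.host)
        host_rel = io.to_relative(counts.subset_samples(host_ids))
        reps = st.robustness_replicates(
            host_rel, n_boot=cfg.n_boot, r_threshold=cfg.network_r,
            p_threshold=cfg.network_p, seed=seed, grid_step=cfg.robustness_grid)
        reg_rows = []
        for gname in ("total-core", "SU+ES", "EC"):
            gx = groups_ab[gname]
            for metric in ("avd", "association_strength"):
                res = st.stability_regression(gx.loc[host_ids],
                                              stability_df.loc[host_ids, metric])
                reg_rows.append({"group": gname, "metric": metric, "slope": res.slope,
                                 "r2": res.r2, "p": res.p, "n": res.n_used})
            boot_x = np.array([
                gx.loc[host_rel.data.index[idx]].mean()
                for idx in reps["sample_indices"]
            ])
            res = st.stability_regression(
                pd.Series(boot_x, name="x"), reps["robustness"].rename("y"))
            reg_rows.append({"group": gname, "metric": "robustness", "slope": res.slope,
                             "r2": res.r2, "p": res.p, "n": res.n_used})
        _write(pd.DataFrame(reg_rows).set_index(["group", "metric"]),
               out / "stability_regressions.tsv")
        results["stability"] = {"n_regressions": len(reg_rows)}
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e)

    # ---- path models -------------------------------------------------------
    stage = "path_model"
    try:
        host_ids = meta.samples_in(cfg.host)
        plot_of = meta.data["plot"]
        prof = pd.read_csv(out / "diversity_profile.tsv", sep="\t", index_col=0)
        conv = {h: {} for h in io.HABITATS if h != cfg.host}
        for sid in counts.sample_ids:
            hab = meta.habitat_of(sid)
            if hab in conv:
                conv[hab][plot_of[sid]] = prof.loc[sid, "nri"]
        frames = []
        for sid in host_ids:
            plot = plot_of[sid]
            frames.append({
                "sample_id": sid,
                "pH": meta.data.at[sid, "pH"],
                "elevation": meta.data.at[sid, "elevation"],
                "litter_convergence": conv.get("litter", {}).get(plot, np.nan),
                "soil_convergence": conv.get("soil", {}).get(plot, np.nan),
                "structure": nmds1.get(sid, np.nan) if nmds1 is not None else np.nan,
                "function": meta.data.at[sid, "pathway_carbon_energy"]
                if "pathway_carbon_energy" in meta.data.columns else np.nan,
            })
        path_df = pd.DataFrame(frames).set_index("sample_id")
        fits = {}
        if path_df[["function"]].notna().all().all():
            for gname in ("total-core", "SU+ES", "EC"):
                data = path_df.copy()
                data["core"] = groups_ab[gname].loc[data.index]
                spec = _default_path_spec(cfg)
                data = data.dropna()
                fit = pm.fit_paths(spec, data)
                accept = pm.evaluate_fit(fit)
                safe = gname.replace("+", "_")
                _write(fit.coefficients.set_index(["from", "to"]),
                       out / f"path_coefficients_{safe}.tsv")
                fits[gname] = {"fisher_c": fit.fisher_c, "df": fit.df, "p": fit.p,
                               "accept": bool(accept)}
        else:
            warnings.warn("no per-sample function column; path models skipped")
        results["path_model"] = fits
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e)

    # ---- manifest ----------------------------------------------------------
    # input/output paths are excluded so that runs into different directories
    # of the same inputs produce identical manifests
    cfg_dict = {k: v for k, v in cfg.to_dict().items()
                if k not in ("outdir", "counts", "meta", "tree", "path_spec")}
    manifest = {
        "config": cfg_dict,
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("prep", "diversity", "ncm", "core", "structure",
                                  "stability", "path_model")},
        "results": results,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return manifest


def _default_path_spec(cfg: PipelineConfig) -> pm.PathModelSpec:
    if cfg.path_spec:
        return pm.PathModelSpec.read(cfg.path_spec)
    return pm.PathModelSpec([
        ("pH", "core"),
        ("elevation", "core"),
        ("litter_convergence", "core"),
        ("soil_convergence", "core"),
        ("core", "structure"),
        ("structure", "function"),
        ("pH", "function"),
        ("elevation", "function"),
    ])
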