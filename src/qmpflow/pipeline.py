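"""End-to-end orchestration of the full analysis over a synthetic study.

``run_pipeline`` executes the stages in dependency order —
quantify -> structure -> community types -> source tracking -> assembly
-> occurrence -> co-occurrence networks -> metabolome -> integration —
writing every stage's tables under a run directory together with a
manifest (seeds, parameters, stage status). Outputs are bit-reproducible
from the same config + seed. A failing stage halts its dependents while
independent stages continue.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assembly, commtypes, conetwork, integrate, metabolome
from . import occurrence as occ
from . import quantify, sourcetrack, structure, synthio
from .tables import write_feature_table


def _stage_seed(master: int, stage: str) -> int:
    """Stage seed derived from the master seed by stable name hashing."""
    h = 2166136261
    for ch in stage.encode():
        h = ((h ^ ch) * 16777619) % (2**31 - 1)
    return (master * 2654435761 + h) % (2**31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str | Path = "results/run"
    seed: int = 7
    sim: synthio.SimConfig | None = None
    stages: tuple = (
        "quantify", "structure", "commtypes", "sourcetrack", "assembly",
        "occurrence", "conetwork", "metabolome", "integrate",
    )
    # stage parameters (desk-scale defaults; see docs/methods.md)
    n_perm: int = 199
    n_null: int = 199
    rc_null: int = 99
    max_assembly_pairs: int = 60
    dmm_k_range: tuple = (1, 2, 3, 4, 5)
    dmm_restarts: int = 2
    k_clusters: int = 6
    top_fraction: float = 0.01
    mmvec_epochs: int = 300
    extra: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage on a freshly simulated study.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim or synthio.SimConfig(seed=_stage_seed(config.seed, "simulate"))
    study = synthio.simulate_study(sim_cfg)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "sim_seed": sim_cfg.seed,
        "stages": {},
        "parameters": {
            "n_perm": config.n_perm, "n_null": config.n_null,
            "rc_null": config.rc_null, "max_assembly_pairs": config.max_assembly_pairs,
            "dmm_k_range": list(config.dmm_k_range), "k_clusters": config.k_clusters,
            "top_fraction": config.top_fraction,
        },
    }
    state: dict = {"study": study}
    deps = {
        "quantify": [],
        "structure": ["quantify"],
        "commtypes": ["quantify"],
        "sourcetrack": [],
        "assembly": [],
        "occurrence": ["quantify"],
        "conetwork": ["quantify"],
        "metabolome": [],
        "integrate": ["quantify", "metabolome"],
    }
    runners = {
        "quantify": _run_quantify,
        "structure": _run_structure,
        "commtypes": _run_commtypes,
        "sourcetrack": _run_sourcetrack,
        "assembly": _run_assembly,
        "occurrence": _run_occurrence,
        "conetwork": _run_conetwork,
        "metabolome": _run_metabolome,
        "integrate": _run_integrate,
    }
    # persist the simulated inputs
    for domain, table in study.tables.items():
        write_feature_table(table, out / f"sim_counts_{domain}.tsv")
    study.tables["bacteria"].meta.to_csv(out / "sim_metadata.tsv", sep="\t")
    study.loads.to_csv(out / "sim_loads.tsv", sep="\t", index=False)
    for domain, tree in study.trees.items():
        (out / f"sim_tree_{domain}.nwk").write_text(
            tree.as_string(schema="newick")
        )

    failed: set[str] = set()
    for stage in config.stages:
        if any(d in failed or d not in config.stages for d in deps[stage]):
            reason = [d for d in deps[stage] if d in failed or d not in config.stages]
            manifest["stages"][stage] = {
                "status": "skipped", "reason": f"dependency unavailable: {reason}",
            }
            continue
        try:
            info = runners[stage](config, state, out, _stage_seed(config.seed, stage))
            manifest["stages"][stage] = {"status": "ok", **(info or {})}
        except Exception as exc:  # halt dependents, keep independents going
            failed.add(stage)
            manifest["stages"][stage] = {
                "status": "failed", "error": f"{type(exc).__name__}: {exc}",
            }
            (out / f"{stage}.error.log").write_text(traceback.format_exc())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_quantify(config, state, out, seed):
    study = state["study"]
    curve = quantify.fit_standard_curve(
        np.arange(3, 9, dtype=float),
        study.config.curve_intercept
        + study.config.curve_slope * np.arange(3, 9, dtype=float),
    )
    loads = study.loads
    measured = pd.Series(
        quantify.ct_to_load(
            curve, loads.ct.to_numpy(), loads.dilution_factor.to_numpy(),
            loads.sample_weight.to_numpy(),
        ),
        index=loads.sample_id,
        name="load",
    )
    state["qmp"], state["rmp"] = {}, {}
    for domain, table in study.tables.items():
        rmp = quantify.rmp_transform(table)
        qmp = quantify.qmp_transform(table, measured)
        state["rmp"][domain] = rmp
        state["qmp"][domain] = qmp
        write_feature_table(qmp, out / f"qmp_{domain}.tsv")
    state["measured_loads"] = measured
    return {"curve_slope": curve.slope, "curve_efficiency": curve.efficiency}


def _run_structure(config, state, out, seed):
    study = state["study"]
    rows = []
    adjacency = []
    protests = []
    for domain, qmp in state["qmp"].items():
        sh = structure.shannon_per_sample(qmp)
        sh.to_frame().assign(domain=domain).to_csv(
            out / f"shannon_{domain}.tsv", sep="\t"
        )
        dm = structure.bray_curtis_matrix(qmp)
        part = structure.variance_partition(
            dm, qmp.meta, ["bird", "segment", "dph"], n_perm=config.n_perm, seed=seed
        )
        part["domain"] = domain
        rows.append(part)
        for seg in study.config.segments:
            adj = structure.adjacent_time_dissimilarity(qmp, seg)
            med = adj.groupby("interval", sort=False)["bc"].median().rename("median_bc")
            adjacency.append(med.to_frame().assign(domain=domain, segment=seg))
        coords_q, _ = structure.pcoa(structure.bray_curtis_matrix(state["qmp"][domain]))
        coords_r, _ = structure.pcoa(structure.bray_curtis_matrix(state["rmp"][domain]))
        pro = structure.protest(
            coords_q.iloc[:, :2], coords_r.iloc[:, :2], n_perm=config.n_perm, seed=seed
        )
        protests.append({"domain": domain, "m12": pro.m12, "p": pro.p_value})
    pd.concat(rows, ignore_index=True).to_csv(
        out / "variance_partition.tsv", sep="\t", index=False
    )
    pd.concat(adjacency).to_csv(out / "adjacent_time_bc.tsv", sep="\t")
    pd.DataFrame(protests).to_csv(out / "protest_qmp_rmp.tsv", sep="\t", index=False)
    return {}


def _run_commtypes(config, state, out, seed):
    info = {}
    for domain, qmp in state["qmp"].items():
        binned = commtypes.discretize_absolute(qmp)
        best_k, crit, models = commtypes.dmm_select(
            binned, k_range=config.dmm_k_range, seed=seed, n_restarts=config.dmm_restarts
        )
        assignments = models[best_k].assignments()
        freq = commtypes.type_frequencies(assignments, qmp.meta)
        crit.to_csv(out / f"dmm_criteria_{domain}.tsv", sep="\t")
        assignments.to_frame().to_csv(out / f"dmm_assignments_{domain}.tsv", sep="\t")
        freq.to_csv(out / f"dmm_frequencies_{domain}.tsv", sep="\t", index=False)
        info[f"best_k_{domain}"] = best_k
    return info


def _run_sourcetrack(config, state, out, seed):
    study = state["study"]
    frames = []
    for domain, table in study.tables.items():
        res = sourcetrack.adjacent_segment_contribution(table)
        res["domain"] = domain
        frames.append(res)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "source_contributions.tsv", sep="\t", index=False
    )
    return {}


def _run_assembly(config, state, out, seed):
    study = state["study"]
    frames = []
    for domain, table in study.tables.items():
        taxa = list(table.taxa)
        d = assembly.tip_distance_matrix(study.trees[domain], taxa)
        for seg in study.config.segments:
            sub = table.subset(table.meta["segment"] == seg)
            res = assembly.pairwise_assembly(
                sub.data, d, n_null=config.rc_null, seed=seed,
                max_pairs=config.max_assembly_pairs,
            )
            res["domain"], res["segment"] = domain, seg
            frames.append(res)
    allres = pd.concat(frames, ignore_index=True)
    allres.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
    summary = assembly.summarize_processes(allres, ["domain", "segment"])
    summary.to_csv(out / "assembly_summary.tsv", sep="\t", index=False)
    return {"deterministic_mean": float(summary["deterministic"].mean())}


def _run_occurrence(config, state, out, seed):
    study = state["study"]
    frames, censuses = [], []
    for domain, qmp in state["qmp"].items():
        long_df, census, _ = occ.pattern_census(qmp, list(study.config.segments))
        long_df["domain"] = domain
        census["domain"] = domain
        frames.append(long_df)
        censuses.append(census)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "occurrence_patterns.tsv", sep="\t", index=False
    )
    pd.concat(censuses, ignore_index=True).to_csv(
        out / "occurrence_census.tsv", sep="\t", index=False
    )
    return {}


def _run_conetwork(config, state, out, seed):
    study = state["study"]
    nets = []
    consistency = {}
    for seg in study.config.segments:
        # bacteria and fungi pooled into one per-segment network
        joint_q = _pooled_segment_table(state["qmp"], seg)
        joint_r = _pooled_segment_table(state["rmp"], seg)
        fq = conetwork.prevalence_filter(joint_q)
        fr = conetwork.prevalence_filter(joint_r)
        net_q = conetwork.build_network(fq, segment=seg)
        net_r = conetwork.build_network(fr, segment=seg)
        nets.append(net_q)
        net_q.edges.assign(segment=seg, mode="QMP").to_csv(
            out / f"network_edges_{seg}.tsv", sep="\t", index=False
        )
        cons = conetwork.qmp_rmp_consistency(net_q, net_r)
        consistency[seg] = cons.consistency_pct
    topo = pd.DataFrame(
        [{"segment": n.segment, **vars(conetwork.topology(n))} for n in nets]
    )
    topo.to_csv(out / "network_topology.tsv", sep="\t", index=False)
    key = pd.concat(
        [conetwork.keystone(n).assign(segment=n.segment) for n in nets],
        ignore_index=True,
    )
    key.to_csv(out / "network_keystone.tsv", sep="\t", index=False)
    _, sharing = conetwork.edge_sharing(nets)
    sharing.to_csv(out / "network_edge_sharing.tsv", sep="\t", index=False)
    pd.Series(consistency, name="consistency_pct").to_csv(
        out / "network_consistency.tsv", sep="\t"
    )
    state["networks"] = nets
    return {"consistency_pct": consistency}


def _pooled_segment_table(tables: dict, segment: str):
    from .tables import FeatureTable

    parts = []
    meta = None
    for domain, t in tables.items():
        sub = t.subset(t.meta["segment"] == segment)
        d = sub.data.copy()
        d.index = [f"{b}_{p}" for b, p in zip(sub.meta.bird, sub.meta.dph)]
        parts.append(d)
        m = sub.meta.copy()
        m.index = d.index
        meta = m if meta is None else meta
    joint = pd.concat(parts, axis=1)
    return FeatureTable(joint, meta.loc[joint.index], None, list(tables.values())[0].mode)


def _run_metabolome(config, state, out, seed):
    study = state["study"]
    table, filt_log = metabolome.filter_features(
        study.metabolites, study.metabolite_dph, study.metabolite_taxonomy
    )
    assoc = metabolome.glm_time_association(table)
    assoc.to_csv(out / "metabolite_time_association.tsv", sep="\t")
    groups = table.dph.astype(str)
    opls = metabolome.opls_da(table, groups)
    opls.vip.to_frame().to_csv(out / "metabolite_vip.tsv", sep="\t")
    clusters = metabolome.cluster_trajectories(
        table, metabolites=assoc.index[assoc.associated], k=config.k_clusters
    )
    clusters.labels.to_frame().to_csv(out / "metabolite_clusters.tsv", sep="\t")
    comp = metabolome.cluster_composition(clusters, study.metabolite_taxonomy)
    comp.to_csv(out / "metabolite_cluster_composition.tsv", sep="\t")
    state["metabolome"] = {"table": table, "assoc": assoc, "clusters": clusters}
    return {"n_associated": int(assoc.associated.sum()), **filt_log}


def _run_integrate(config, state, out, seed):
    study = state["study"]
    met = state["metabolome"]["table"]
    clusters = state["metabolome"]["clusters"]
    parts = {}
    labels_rows = []
    for domain, qmp in state["qmp"].items():
        for seg in study.config.segments:
            sub = qmp.subset(qmp.meta["segment"] == seg)
            microbes = sub.data.copy()
            microbes.index = [
                f"{b}_{d:02d}d_serum" for b, d in zip(sub.meta.bird, sub.meta.dph)
            ]
            microbes = microbes.loc[microbes.index.intersection(met.data.index)]
            microbes = microbes.loc[:, microbes.sum(axis=0) > 0]
            # restrict to clustered (time-associated) metabolites
            mets = met.data.loc[microbes.index, clusters.labels.index]
            fit = integrate.mmvec_fit(
                microbes, mets, epochs=config.mmvec_epochs, seed=seed
            )
            sel = integrate.select_top(fit, fraction=config.top_fraction)
            parts[(seg, domain)] = sel
            for taxon in microbes.columns:
                labels_rows.append({"microbe": taxon, "segment": seg, "domain": domain})
    merged = integrate.merge_selections(parts)
    merged.to_csv(out / "interactions_top.tsv", sep="\t", index=False)
    ratio = integrate.ratio_table(
        merged,
        pd.DataFrame(labels_rows).drop_duplicates().set_index("microbe"),
        clusters.labels,
    )
    ratio.to_csv(out / "interaction_ratio.tsv", sep="\t", index=False)
    _, deg, cats = integrate.interaction_network(merged, study.metabolite_taxonomy)
    deg.to_csv(out / "interaction_degree.tsv", sep="\t", index=False)
    cats.to_csv(out / "interaction_categories.tsv", sep="\t", index=False)
    return {"n_retained": len(merged)}
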