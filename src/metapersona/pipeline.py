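"""End-to-end pipeline orchestration.

Stages, in order: divergence coding -> per-sample reaction states -> iMAT
context networks -> FVA flux profiles and activity calls -> clustering ->
activity statistics -> single-gene deletions and essential genes -> drug
association scoring -> (optional) methylation and survival.  Every stage
writes TSV/JSON outputs into the run directory, and a ``manifest.json``
records the configuration hash, seeds, per-stage outputs, warnings and
timings.  Reruns with the same configuration produce byte-identical stage
outputs (the manifest's timings are the only nondeterministic field).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cbm import essential_genes, single_gene_deletion_all
from .cluster import (elbow_wss, kaplan_meier, kmeans_cluster,
                      knee_by_second_difference, merge_clusters, pca_embed)
from .divergence import divergence_pipeline
from .drugs import DrugScreen, drug_association
from .imat import (ImatConfig, classify_active, extract_context_network,
                   reaction_states_from_genes, solve_imat)
from .io import read_media, read_model, write_model
from .methylation import joint_divergence_proportion, methylation_divergence
from .model import apply_media
from .simulate import (SimConfig, default_media, make_toy_model,
                       simulate_drug_screen, simulate_expression,
                       simulate_methylation, simulate_survival)
from .stats import chi_squared, differential_reactions, essentiality_comparison, \
    subsystem_enrichment

log = logging.getLogger("metapersona")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimConfig overrides; presence means inputs are generated
    "divergence": {"gamma": 0.9},
    "imat": {"epsilon": 1.0, "tol": 1e-6, "objective_fraction": 0.9,
             "time_limit": 60.0},
    "fva": {"fraction": 0.9},
    "clustering": {"k": 4, "k_min": 1, "k_max": 8, "n_init": 25},
    "stats": {"p_threshold": 0.05, "fdr": 0.05},
    "deletion": {"grratio_threshold": 0.9},
    "drugs": {"alpha": 1e-3, "gene_set": "per-sample"},
    "survival": {"merge": None},
    "methylation": {"gamma": 0.9},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config, sort_keys=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "seed": config["seed"],
        "stages": [],
        "warnings": [],
    }
    caught: list[str] = []

    def stage(name: str):
        log.info("stage %s", name)
        t0 = time.time()

        def done(outputs: list[str]) -> None:
            manifest["stages"].append({
                "name": name,
                "outputs": outputs,
                "seconds": round(time.time() - t0, 3),
            })

        return done

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            _run_stages(config, out, manifest, stage)
        except Exception:
            (out / "manifest.json.partial").write_text(
                json.dumps(manifest, indent=1))
            raise
        caught = sorted({str(w.message) for w in wlist})
    manifest["warnings"] = caught
    (out / "manifest.json.partial").unlink(missing_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def _run_stages(config: dict, out: Path, manifest: dict, stage) -> None:
    seed = int(config["seed"])

    # ------------------------------------------------------------------ inputs
    done = stage("inputs")
    inputs = config.get("inputs") or {}
    if "simulate" in config and config["simulate"] is not None and not inputs:
        sim = SimConfig(seed=seed, **config["simulate"])
        model = make_toy_model(sim)
        media = default_media(model, uptake=sim.uptake_bound)
        expression, labels, truth = simulate_expression(model, sim)
        mutation, ic50, drug_truth = simulate_drug_screen(sim)
        beta, cpg_map = simulate_methylation(expression, sim)
        survival = simulate_survival(labels, sim)
        (out / "inputs").mkdir(parents=True, exist_ok=True)
        write_model(model, out / "inputs" / "model.json")
        _write_tsv(expression, out / "inputs" / "expression.tsv")
        _write_tsv(labels.to_frame(), out / "inputs" / "phenotype.tsv")
        _write_tsv(mutation, out / "inputs" / "mutation.tsv")
        _write_tsv(ic50, out / "inputs" / "ic50.tsv")
        _write_tsv(beta, out / "inputs" / "methylation_beta.tsv")
        _write_tsv(cpg_map, out / "inputs" / "cpg_map.tsv")
        _write_tsv(survival, out / "inputs" / "survival.tsv")
        (out / "inputs" / "truth.json").write_text(json.dumps({
            "cluster_gene_sets": truth["cluster_gene_sets"],
            "essential_genes": truth["essential_genes"],
            "planted_drug_pairs": drug_truth["planted_pairs"],
        }, indent=1, default=str) + "\n")
        truth_labels = labels
    else:
        model = read_model(inputs["model"])
        media = read_media(inputs["media"]) if inputs.get("media") else {}
        expression = pd.read_csv(inputs["expression"], sep="\t", index_col=0)
        truth_labels = pd.read_csv(inputs["phenotype"], sep="\t",
                                   index_col=0).iloc[:, 0]
        mutation = ic50 = beta = cpg_map = survival = None
        if inputs.get("mutation") and inputs.get("ic50"):
            mutation = pd.read_csv(inputs["mutation"], sep="\t", index_col=0)
            ic50 = pd.read_csv(inputs["ic50"], sep="\t", index_col=0)
        if inputs.get("methylation_beta") and inputs.get("cpg_map"):
            beta = pd.read_csv(inputs["methylation_beta"], sep="\t", index_col=0)
            cpg_map = pd.read_csv(inputs["cpg_map"], sep="\t", index_col=0)
        if inputs.get("survival"):
            survival = pd.read_csv(inputs["survival"], sep="\t", index_col=0)
    model = apply_media(model, media)
    done(["inputs/"])

    # -------------------------------------------------------------- divergence
    done = stage("divergence")
    gamma = float(config["divergence"]["gamma"])
    normal_ids = [s for s in truth_labels.index if truth_labels[s] == "normal"]
    ternary, baseline, heldout = divergence_pipeline(
        expression, normal_ids, gamma=gamma, seed=seed)
    _write_tsv(ternary, out / "divergence" / "ternary.tsv")
    _write_tsv(pd.DataFrame({"lower": baseline.lower, "upper": baseline.upper}),
               out / "divergence" / "baseline.tsv")
    (out / "divergence" / "reference_ids.txt").write_text(
        "\n".join(baseline.reference_ids) + "\n")
    done(["divergence/ternary.tsv", "divergence/baseline.tsv"])

    # --------------------------------------------------------- reaction states
    done = stage("reaction_states")
    model_genes = [g for g in ternary.index if g in set(model.gene_ids)]
    states = reaction_states_from_genes(model, ternary.loc[model_genes])
    _write_tsv(states, out / "networks" / "reaction_states.tsv")
    done(["networks/reaction_states.tsv"])

    # ------------------------------------------- iMAT networks + FVA + deletion
    done = stage("context_networks")
    icfg = ImatConfig(**{k: float(v) for k, v in config["imat"].items()})
    fraction = float(config["fva"]["fraction"])
    grr_cut = float(config["deletion"]["grratio_threshold"])
    net_states = {}
    scores = {}
    max_flux = {}
    activity = {}
    gr_ratios = {}
    ess_sets: dict[str, set[str]] = {}
    for sample in states.columns:
        sol = solve_imat(model, states[sample], icfg)
        net = extract_context_network(model, sol, icfg, sample)
        ctx = net.context_model(model)
        act = classify_active(ctx, fraction=fraction, tol=icfg.tol)
        deletion = single_gene_deletion_all(ctx)
        net_states[sample] = net.states
        scores[sample] = sol.score
        max_flux[sample] = act["max_flux"].reindex(model.reaction_ids).fillna(0.0)
        activity[sample] = act["active"].reindex(model.reaction_ids) \
            .fillna(0).astype(int)
        gr = deletion.table["gr_ratio"].reindex(model.gene_ids).fillna(1.0)
        gr_ratios[sample] = gr
        ess_sets[sample] = essential_genes(deletion, grr_cut)
    states_df = pd.DataFrame(net_states)
    activity_df = pd.DataFrame(activity)
    profiles = pd.DataFrame(max_flux).T  # samples x reactions
    grr_df = pd.DataFrame(gr_ratios)
    _write_tsv(states_df, out / "networks" / "retained.tsv")
    _write_tsv(pd.Series(scores, name="score").to_frame(),
               out / "networks" / "imat_scores.tsv")
    _write_tsv(profiles, out / "fva" / "max_flux.tsv")
    _write_tsv(activity_df, out / "fva" / "activity.tsv")
    _write_tsv(grr_df, out / "deletions" / "grratio.tsv")
    (out / "deletions" / "essential_sets.json").write_text(json.dumps(
        {s: sorted(g) for s, g in ess_sets.items()}, indent=1) + "\n")
    done(["networks/retained.tsv", "fva/max_flux.tsv", "fva/activity.tsv",
          "deletions/grratio.tsv"])

    # --------------------------------------------------------------- clustering
    done = stage("clustering")
    ccfg = config["clustering"]
    tumor_ids = [s for s in profiles.index if truth_labels.get(s) != "normal"]
    wss = elbow_wss(profiles.loc[tumor_ids],
                    range(int(ccfg["k_min"]), int(ccfg["k_max"]) + 1),
                    seed=seed, n_init=int(ccfg["n_init"]))
    assignment = kmeans_cluster(profiles.loc[tumor_ids], int(ccfg["k"]),
                                seed=seed, n_init=int(ccfg["n_init"]))
    clusters = pd.Series(0, index=profiles.index, name="cluster")
    clusters.loc[tumor_ids] = assignment.labels
    scores_pca, evr = pca_embed(profiles)
    _write_tsv(clusters.to_frame(), out / "clustering" / "clusters.tsv")
    _write_tsv(wss.to_frame(), out / "clustering" / "wss.tsv")
    _write_tsv(scores_pca, out / "clustering" / "pca.tsv")
    knee = knee_by_second_difference(wss)
    done(["clustering/clusters.tsv", "clustering/wss.tsv"])
    manifest["elbow_knee_k"] = knee

    # ------------------------------------------------------------------- stats
    done = stage("activity_stats")
    p_thr = float(config["stats"]["p_threshold"])
    group = pd.Series(np.where([truth_labels.get(s) == "normal"
                                for s in activity_df.columns],
                               "normal", "cancer"),
                      index=activity_df.columns)
    diff = differential_reactions(activity_df, group, "cancer", "normal")
    submap = pd.Series(model.subsystem, index=model.reaction_ids)
    enrich = subsystem_enrichment(diff, submap, p_threshold=p_thr)
    _write_tsv(diff, out / "stats" / "differential_reactions.tsv")
    _write_tsv(enrich, out / "stats" / "subsystem_enrichment.tsv")
    per_cluster = []
    for c in sorted(set(assignment.labels)):
        grp_c = pd.Series("other", index=activity_df.columns)
        grp_c[clusters == c] = "cluster"
        grp_c[clusters == 0] = "normal"
        d = differential_reactions(activity_df, grp_c, "cluster", "normal")
        per_cluster.append((c, int((d["p"] < p_thr).sum())))
        _write_tsv(d, out / "stats" / f"differential_cluster{c}_vs_normal.tsv")
    # cluster-phenotype association
    tumor_truth = truth_labels.reindex(tumor_ids).astype(str)
    table = pd.crosstab(tumor_truth, assignment.labels)
    chi_stat, chi_p = chi_squared(table.to_numpy())
    (out / "stats" / "cluster_phenotype_chi2.json").write_text(json.dumps(
        {"statistic": chi_stat, "p": chi_p}, indent=1) + "\n")
    done(["stats/differential_reactions.tsv", "stats/subsystem_enrichment.tsv"])
    manifest["n_differential_reactions"] = int((diff["p"] < p_thr).sum())

    # --------------------------------------------------- essentiality contrast
    done = stage("essentiality")
    ess_cmp = essentiality_comparison(grr_df, group, "cancer", "normal")
    _write_tsv(ess_cmp, out / "deletions" / "essentiality_comparison.tsv")
    done(["deletions/essentiality_comparison.tsv"])

    # ------------------------------------------------------------ drug scoring
    done = stage("drug_scoring")
    if mutation is not None:
        screen = DrugScreen(mutation, ic50)
        dcfg = config["drugs"]
        if dcfg.get("gene_set") == "global":
            sig_genes = set(ess_cmp.index[ess_cmp["q"] < float(config["stats"]["fdr"])])
            sets = {s: sig_genes for s in ess_sets}
        else:
            sets = ess_sets
        scores_tbl = drug_association(sets, screen, alpha=float(dcfg["alpha"]))
        _write_tsv(scores_tbl.ranking, out / "drugs" / "ranking.tsv")
        _write_tsv(scores_tbl.per_sample.set_index("sample"),
                   out / "drugs" / "per_sample.tsv")
        done(["drugs/ranking.tsv", "drugs/per_sample.tsv"])
    else:
        done([])

    # ------------------------------------------------------------- methylation
    done = stage("methylation")
    if beta is not None:
        mgamma = float(config["methylation"]["gamma"])
        meth_tern = methylation_divergence(beta, normal_ids, gamma=mgamma)
        joint = joint_divergence_proportion(ternary, meth_tern, cpg_map)
        _write_tsv(joint, out / "methylation" / "joint_divergence.tsv")
        done(["methylation/joint_divergence.tsv"])
    else:
        done([])

    # ---------------------------------------------------------------- survival
    done = stage("survival")
    if survival is not None:
        merge = config["survival"].get("merge")
        surv_groups = clusters.reindex(survival.index).dropna().astype(int)
        surv = survival.loc[surv_groups.index]
        if merge:
            merged = merge_clusters(surv_groups, {int(k): v for k, v in merge.items()})
        else:
            merged = surv_groups
        km = kaplan_meier(surv, merged)
        _write_tsv(km.set_index("group"), out / "survival" / "kaplan_meier.tsv")
        done(["survival/kaplan_meier.tsv"])
    else:
        done([])
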