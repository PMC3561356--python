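"""End-to-end orchestration: simulate -> normalize -> differential
expression -> time-course selection -> clustering -> enrichment ->
cross-species concordance, under a single YAML config with one global
seed.  Stage-specific seeds are derived deterministically from the
global seed, so an identical config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import clustering, concordance, diffexpr, enrichment, preprocess
from .io_core import (
    AnalysisConfig,
    ExpressionMatrix,
    SampleDesign,
    ValidationError,
    read_expression_matrix,
    read_gene_sets,
    read_ortholog_map,
    read_sample_design,
    write_expression_matrix,
    write_json_report,
)
from .synthetic_data import SimConfig, simulate_experiment

logger = logging.getLogger("colicord")

STAGES = (
    "simulate",
    "normalize",
    "diffexp",
    "timecourse",
    "cluster",
    "enrich",
    "concordance",
)

RAT_CONTRASTS = (("T3", "T0"), ("T7", "T0"), ("T12", "T0"))
HUMAN_CONTRASTS = (("UC", "N"), ("CD", "N"))

# Assumption flags echoed into every run report so downstream consumers
# see which conventions produced the numbers.
ASSUMPTIONS = {
    "probe_collapse": "highest-mean probe per gene",
    "timecourse_selection": (
        "max moderated paired t with within-subject permutation p "
        "(stand-in for Bayesian time-course selection)"
    ),
    "gene_rho_universe": "Spearman rho over all joined ortholog pairs",
    "pathway_namespace": "rat fold changes translated to human ids via orthologs",
    "pathway_concordance_rule": "sign agreement of mean pathway log2 fold change",
}


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % 2**31)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "stages" not in cfg:
        cfg["stages"] = list(STAGES)
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    return cfg


def run_pipeline(config: str | Path | Mapping, outdir: str | Path) -> dict:
    """Run the configured stages; returns (and writes) the run report.

    Partial failure leaves completed stage outputs on disk and records
    the failing stage and cause in the report before re-raising.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    analysis = AnalysisConfig.from_dict(
        {**config.get("analysis", {}), "rng_seed": _derive_seed(seed, 1)}
    )
    report: dict = {
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "assumptions": ASSUMPTIONS,
        "stages": [],
        "warnings": [],
        "manifest": [],
    }
    state: dict = {}

    def record(stage: str, n_in: int, n_out: int, outputs: list[str]) -> None:
        # manifest paths are stored relative to outdir so a report is
        # independent of where the run directory lives
        rel = []
        for o in outputs:
            try:
                rel.append(str(Path(o).relative_to(outdir)))
            except ValueError:
                rel.append(str(o))
        report["stages"].append(
            {"stage": stage, "n_in": n_in, "n_out": n_out, "outputs": rel}
        )
        report["manifest"].extend(rel)

    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            logger.info("running stage %s", stage)
            if stage == "simulate":
                _stage_simulate(config, seed, outdir, state, record)
            elif stage == "normalize":
                _stage_normalize(config, outdir, state, record)
            elif stage == "diffexp":
                _stage_diffexp(outdir, state, record)
            elif stage == "timecourse":
                _stage_timecourse(analysis, outdir, state, record, report)
            elif stage == "cluster":
                _stage_cluster(analysis, outdir, state, record, report)
            elif stage == "enrich":
                _stage_enrich(analysis, outdir, state, record, report)
            elif stage == "concordance":
                _stage_concordance(analysis, outdir, state, record, report)
    except Exception as exc:
        report["error"] = {"stage": stage, "cause": str(exc)}
        write_json_report(report, outdir / "run_report.json")
        raise
    write_json_report(report, outdir / "run_report.json")
    return report


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise ValidationError(f"stage {stage!r} requires missing input {key!r}")
    return state[key]


def _stage_simulate(config, seed, outdir, state, record) -> None:
    sim_cfg = SimConfig(
        **{**config.get("sim", {}), "rng_seed": _derive_seed(seed, 0)}
    )
    study = simulate_experiment(sim_cfg)
    paths = study.write(outdir / "sim")
    state.update(
        rat_expr=study.rat_expr,
        rat_design=study.rat_design,
        human_expr=study.human_expr,
        human_design=study.human_design,
        orthologs=study.orthologs,
        go_sets=study.go_sets,
        pathway_sets=study.pathway_sets,
        truth=study.truth,
    )
    record("simulate", 0, study.rat_expr.shape[0], sorted(paths.values()))


def _load_inputs(config, state) -> None:
    inputs = config.get("inputs", {})
    if "rat_expr" in inputs and "rat_expr" not in state:
        state["rat_expr"] = read_expression_matrix(inputs["rat_expr"], scale_hint="raw")
        state["rat_design"] = read_sample_design(inputs["rat_design"])
    if "human_expr" in inputs and "human_expr" not in state:
        state["human_expr"] = read_expression_matrix(inputs["human_expr"], scale_hint="raw")
        state["human_design"] = read_sample_design(inputs["human_design"])
    if "orthologs" in inputs and "orthologs" not in state:
        state["orthologs"], _ = read_ortholog_map(
            inputs["orthologs"], namespace_a="rat", namespace_b="human"
        )
    if "go_sets" in inputs and "go_sets" not in state:
        state["go_sets"], _ = read_gene_sets(inputs["go_sets"])
    if "pathway_sets" in inputs and "pathway_sets" not in state:
        state["pathway_sets"], _ = read_gene_sets(inputs["pathway_sets"])


def _stage_normalize(config, outdir, state, record) -> None:
    _load_inputs(config, state)
    n_in = n_out = 0
    outputs = []
    for species in ("rat", "human"):
        key = f"{species}_expr"
        if key not in state:
            continue
        m = state[key]
        n_in += m.shape[0]
        norm = preprocess.quantile_normalize(m)
        if norm.scale == "raw":
            norm = preprocess.log2_transform(norm)
        state[f"{species}_norm"] = norm
        path = outdir / f"{species}_normalized.tsv"
        write_expression_matrix(norm, path)
        outputs.append(str(path))
        n_out += norm.shape[0]
    if not outputs:
        raise ValidationError("stage 'normalize' requires missing input 'rat_expr' or 'human_expr'")
    record("normalize", n_in, n_out, outputs)


def _stage_diffexp(outdir, state, record) -> None:
    n_in = n_out = 0
    outputs = []
    for species, contrasts, design_key in (
        ("rat", RAT_CONTRASTS, "rat_design"),
        ("human", HUMAN_CONTRASTS, "human_design"),
    ):
        norm = state.get(f"{species}_norm")
        if norm is None:
            continue
        design = _require(state, design_key, "diffexp")
        for cond_a, cond_b in contrasts:
            de = diffexpr.differential_expression(norm, design, cond_a, cond_b)
            state[f"de_{species}_{cond_a}_vs_{cond_b}"] = de
            path = outdir / f"de_{species}_{cond_a}_vs_{cond_b}.tsv"
            de.to_csv(path, sep="\t")
            outputs.append(str(path))
            n_in += de.shape[0]
            n_out += de.shape[0]
    if not outputs:
        raise ValidationError("stage 'diffexp' requires missing input 'rat_norm' or 'human_norm'")
    record("diffexp", n_in, n_out, outputs)


def _stage_timecourse(analysis, outdir, state, record, report) -> None:
    norm = _require(state, "rat_norm", "timecourse")
    design = _require(state, "rat_design", "timecourse")
    sel = diffexpr.timecourse_select(norm, design, analysis)
    report["warnings"].extend(sel.warnings)
    state["timecourse"] = sel
    path = outdir / "timecourse_selection.tsv"
    sel.table.to_csv(path, sep="\t")
    record("timecourse", sel.table.shape[0], int(sel.table["selected"].sum()), [str(path)])


def _stage_cluster(analysis, outdir, state, record, report) -> None:
    norm = _require(state, "rat_norm", "cluster")
    design = _require(state, "rat_design", "cluster")
    sel = _require(state, "timecourse", "cluster")
    genes = sel.selected_genes
    if len(genes) < 2:
        report["warnings"].append("fewer than 2 selected genes; clustering skipped")
        record("cluster", len(genes), 0, [])
        return
    profiles = clustering.mean_condition_profiles(norm.values.loc[genes], design)
    # center profiles on the baseline so shapes, not absolute levels, cluster
    profiles = profiles.sub(profiles.iloc[:, 0], axis=0)
    sim = clustering.profile_similarity(profiles.to_numpy())
    assignment = clustering.affinity_propagation(
        sim,
        preference="median",
        damping=analysis.ap_damping,
        max_iter=analysis.ap_max_iter,
        conv_iter=analysis.ap_conv_iter,
        seed=analysis.rng_seed,
    )
    state["cluster_genes"] = genes
    state["clusters"] = assignment
    out = pd.DataFrame(
        {
            "gene": genes,
            "cluster": assignment.labels,
            "is_exemplar": [
                assignment.exemplars[l] == i for i, l in enumerate(assignment.labels)
            ],
        }
    )
    path = outdir / "clusters.tsv"
    out.to_csv(path, sep="\t", index=False)
    record("cluster", len(genes), assignment.n_clusters, [str(path)])


def _stage_enrich(analysis, outdir, state, record, report) -> None:
    if "clusters" not in state and "timecourse" in state:
        report["warnings"].append("no clusters available; enrichment skipped")
        record("enrich", 0, 0, [])
        return
    assignment = _require(state, "clusters", "enrich")
    genes = _require(state, "cluster_genes", "enrich")
    sets = _require(state, "go_sets", "enrich")
    norm = _require(state, "rat_norm", "enrich")
    table = enrichment.enrich_clusters(
        assignment, genes, sets, reference=norm.gene_ids, cfg=analysis
    )
    path = outdir / "enrichment.tsv"
    table.to_csv(path, sep="\t", index=False)
    record("enrich", assignment.n_clusters, table.shape[0], [str(path)])


def _stage_concordance(analysis, outdir, state, record, report) -> None:
    omap = _require(state, "orthologs", "concordance")
    pathway_sets = _require(state, "pathway_sets", "concordance")
    outputs = []
    summaries = {}
    n_in = n_out = 0
    for rc_a, rc_b in RAT_CONTRASTS:
        rat_de = state.get(f"de_rat_{rc_a}_vs_{rc_b}")
        if rat_de is None:
            raise ValidationError("stage 'concordance' requires missing input 'diffexp' rat tables")
        rat_de_h = concordance.translate_to_human(rat_de, omap)
        rat_pfc = concordance.pathway_fold_changes(rat_de_h, pathway_sets, analysis)
        for hc_a, hc_b in HUMAN_CONTRASTS:
            human_de = state.get(f"de_human_{hc_a}_vs_{hc_b}")
            if human_de is None:
                raise ValidationError(
                    "stage 'concordance' requires missing input 'diffexp' human tables"
                )
            tag = f"{rc_a}_vs_{hc_a}"
            joined = concordance.join_orthologs(rat_de, human_de, omap)
            gene_table, summary = concordance.classify_concordance(joined, analysis)
            path = outdir / f"concordance_genes_{tag}.tsv"
            gene_table.to_csv(path, sep="\t", index=False)
            outputs.append(str(path))
            human_pfc = concordance.pathway_fold_changes(human_de, pathway_sets, analysis)
            pc = concordance.pathway_concordance(rat_pfc, human_pfc)
            ppath = outdir / f"concordance_pathways_{tag}.tsv"
            pc.table.to_csv(ppath, sep="\t")
            outputs.append(str(ppath))
            summaries[tag] = {
                "gene_rho": None if summary.rho_undefined else summary.rho,
                "gene_rho_p": None if summary.rho_undefined else summary.rho_p,
                "n_pairs": summary.n_pairs,
                "n_concordant_up": summary.n_concordant_up,
                "n_concordant_down": summary.n_concordant_down,
                "pathway_rho": None if pc.rho.undefined else pc.rho.rho,
                "n_pathways_concordant": pc.n_concordant,
                "n_pathways_nonconcordant": pc.n_nonconcordant,
            }
            n_in += summary.n_pairs
            n_out += summary.n_concordant_up + summary.n_concordant_down
            state[f"concordance_{tag}"] = (gene_table, summary, pc)
    report["concordance_summaries"] = summaries
    record("concordance", n_in, n_out, outputs)
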