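"""End-to-end orchestration of the analysis with a single configuration.

Stage order: simulate (optional) -> preprocess -> module detection -> top
modules per contrast -> per-module ceRNA networks -> aggregation -> two-layer
RWR-M prioritization -> pathway association for the top lncRNAs -> one
classifier per top lncRNA.  Every stage reads and writes declared files under
``out_dir`` so the chained subcommands and :func:`run_all` produce identical
artifacts.  Each stochastic stage consumes a stage-specific child of the
master seed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cerna import CeRNANetwork, CeRNAPair, aggregate_networks, build_module_cerna, enrich_ora
from .classify import build_classifier_report, extract_pair_features
from .coexpression import (
    cluster_modules,
    compute_eigengenes,
    compute_tom,
    merge_modules,
    module_trait_correlation,
    pick_beta,
    signed_adjacency,
    top_modules,
)
from .pathways import GeneSetCollection, filter_gene_sets, pathway_association
from .preprocess import ExpressionDataset, preprocess_pipeline
from .rwrm import (
    MultiplexGraph,
    RWRMParams,
    layer_weights,
    prioritize_lncrnas,
    rwrm_scores,
)
from .simulate import SimulationConfig, generate_dataset

__all__ = ["RunConfig", "RunReport", "run_all", "STAGES"]

log = logging.getLogger("afcerna")

STAGES = ("simulate", "preprocess", "modules", "cerna", "rwrm", "pathways", "classify")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All stage parameters; the defaults mirror the published analysis."""

    out_dir: str = "afcerna_run"
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    # preprocess
    min_count: int = 10
    max_low_fraction: float = 0.8
    n_sv: int = 2
    top_k: int = 5000
    # coexpression
    beta: int | str = 12  # integer or "auto"
    fit_threshold: float = 0.9
    min_module_size: int = 30
    deep_split: int = 2
    cluster_cut_height: float | None = None
    merge_cut_height: float = 0.25
    n_top_modules_per_contrast: int = 2
    # ceRNA
    alpha: float = 0.05
    use_adjusted: bool = False
    # RWR-M
    delta: float = 0.5
    r: float = 0.7
    rwr_tolerance: float = 1e-10
    rwr_max_iter: int = 10_000
    top_lncrnas: int = 2
    # pathways
    gmt_min_size: int = 10
    gmt_max_size: int = 500
    rhythm_coding: str = "ordinal"
    # classifier
    cv_folds: int = 6
    rng_seed: int = 0

    def path(self, name: str) -> Path:
        return Path(self.out_dir) / name

    def validate(self) -> None:
        if self.n_top_modules_per_contrast < 1:
            raise ValueError("n_top_modules_per_contrast must be >= 1")
        if self.top_lncrnas < 1:
            raise ValueError("top_lncrnas must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.beta != "auto" and (int(self.beta) != self.beta or self.beta < 1):
            raise ValueError("beta must be a positive integer or 'auto'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict
    wall_time_s: float

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "stages": self.stages,
            "wall_time_s": self.wall_time_s,
        }


def _require(cfg: RunConfig, name: str, producer: str) -> Path:
    p = cfg.path(name)
    if not p.exists():
        raise FileNotFoundError(
            f"missing input {p}; run the '{producer}' subcommand first"
        )
    return p


def stage_simulate(cfg: RunConfig) -> dict:
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    overrides = dict(cfg.sim_overrides)
    overrides.setdefault("rng_seed", stage_seed(cfg.rng_seed, "simulate"))
    sim_cfg = SimulationConfig(**overrides)
    log.info("simulate: %d genes, %d modules, seed %d",
             sim_cfg.n_genes, sim_cfg.n_modules, sim_cfg.rng_seed)
    ds = generate_dataset(sim_cfg)
    ds.write_all(cfg.out_dir)
    return {
        "n_genes": int(ds.train_counts.shape[0]),
        "n_train_samples": int(ds.train_counts.shape[1]),
        "n_test_samples": int(ds.test_expression.shape[1]),
        "n_planted_pairs": len(ds.truth["planted_pairs"]),
        "hub_lncrna": ds.truth["hub_lncrna"],
    }


def stage_preprocess(cfg: RunConfig) -> dict:
    counts = io.read_expression_tsv(_require(cfg, "train_counts.tsv", "simulate"))
    phen = io.read_phenotype_tsv(_require(cfg, "phenotypes.tsv", "simulate"))
    biotypes = io.read_biotypes_tsv(_require(cfg, "biotypes.tsv", "simulate"))
    ds = ExpressionDataset(counts, biotypes, phen)
    log.info("preprocess: min_count=%d max_low_fraction=%.2f n_sv=%d top_k=%d",
             cfg.min_count, cfg.max_low_fraction, cfg.n_sv, cfg.top_k)
    cleaned, info = preprocess_pipeline(
        ds,
        min_count=cfg.min_count,
        max_low_fraction=cfg.max_low_fraction,
        n_sv=cfg.n_sv,
        top_k=cfg.top_k,
    )
    io.write_expression_tsv(cleaned.matrix, cfg.path("cleaned_expression.tsv"))
    summary = {k: v for k, v in info.items() if k != "svs"}
    io.write_json(summary, cfg.path("preprocess_summary.json"))
    return summary


def stage_modules(cfg: RunConfig) -> dict:
    expr = io.read_expression_tsv(_require(cfg, "cleaned_expression.tsv", "preprocess"))
    phen = io.read_phenotype_tsv(_require(cfg, "phenotypes.tsv", "simulate"))
    phen = phen.loc[expr.columns]
    biotypes = io.read_biotypes_tsv(_require(cfg, "biotypes.tsv", "simulate"))
    if cfg.beta == "auto":
        beta = pick_beta(expr, fit_threshold=cfg.fit_threshold)
    else:
        beta = int(cfg.beta)
    log.info("modules: beta=%s min_module_size=%d merge_cut=%.2f",
             beta, cfg.min_module_size, cfg.merge_cut_height)
    adjacency = signed_adjacency(expr, beta)
    tom = compute_tom(adjacency)
    assignment = cluster_modules(
        tom,
        min_module_size=cfg.min_module_size,
        deep_split=cfg.deep_split,
        cut_height=cfg.cluster_cut_height,
    )
    assignment = merge_modules(assignment, expr, cut_height=cfg.merge_cut_height)
    out = pd.DataFrame(
        {
            "module": assignment.labels,
            "biotype": biotypes.reindex(assignment.labels.index),
        }
    )
    out.to_csv(cfg.path("module_assignment.tsv"), sep="\t", index_label="gene_id")
    me_frame = assignment.eigengene_frame(expr.columns)
    me_frame.to_csv(cfg.path("eigengenes.tsv"), sep="\t", index_label="sample_id")
    trait: dict = {"beta": beta, "contrasts": {}, "top_modules": {}}
    for contrast in ("susceptibility", "persistence"):
        table = module_trait_correlation(assignment.eigengenes, phen, contrast)
        trait["contrasts"][contrast] = table.to_dict(orient="records")
        trait["top_modules"][contrast] = top_modules(
            table, n_top=cfg.n_top_modules_per_contrast
        )
    io.write_json(trait, cfg.path("module_trait.json"))
    return {
        "beta": beta,
        "n_modules": len(assignment.modules()),
        "n_unassigned": int((assignment.labels == 0).sum()),
        "top_modules": trait["top_modules"],
    }


def stage_cerna(cfg: RunConfig) -> dict:
    assign = pd.read_csv(
        _require(cfg, "module_assignment.tsv", "modules"), sep="\t", index_col=0
    )
    db = io.read_mirna_targets_tsv(_require(cfg, "mirna_targets.tsv", "simulate"))
    seeds = io.read_gene_list(_require(cfg, "seed_genes.txt", "simulate"))
    trait = io.read_json(_require(cfg, "module_trait.json", "modules"))
    selected: list[int] = []
    for contrast in ("susceptibility", "persistence"):
        for m in trait["top_modules"][contrast]:
            if m not in selected:
                selected.append(int(m))
    biotypes = assign["biotype"].to_dict()
    gene_sets = io.read_gmt(_require(cfg, "gene_sets.gmt", "simulate"))
    universe = list(assign.index)
    networks = []
    per_module: dict = {}
    for m in selected:
        genes_m = assign.index[assign["module"] == m].tolist()
        net = build_module_cerna(
            genes_m, biotypes, db, module=m, alpha=cfg.alpha,
            use_adjusted=cfg.use_adjusted,
        )
        networks.append(net)
        io.write_edges_tsv(net.to_frame(), cfg.path(f"cerna_module_{m}.tsv"))
        ora = enrich_ora(net.nodes(), universe, gene_sets) if net.edges else None
        per_module[str(m)] = {
            "n_edges": len(net.edges),
            "n_lncrnas": len(net.lncrnas()),
            "n_mrnas": len(net.mrnas()),
            "top_enriched_set": None if ora is None or ora.empty
            else {"set": ora.iloc[0]["set"], "p": float(ora.iloc[0]["p"])},
        }
    agg = aggregate_networks(networks, seeds)
    io.write_edges_tsv(agg.to_frame(), cfg.path("cerna_aggregated.tsv"))
    summary = {
        "modules": per_module,
        "selected_modules": selected,
        "n_edges_total": len(agg.edges),
        "n_disease_genes_in_network": len(agg.disease_genes),
        "alpha": cfg.alpha,
        "use_adjusted": cfg.use_adjusted,
        "N_mirnas": db.N,
    }
    io.write_json(summary, cfg.path("cerna_summary.json"))
    return summary


def _aggregated_network_from_file(cfg: RunConfig) -> CeRNANetwork:
    df = io.read_edges_tsv(_require(cfg, "cerna_aggregated.tsv", "cerna"))
    edges = [
        CeRNAPair(
            row["lncRNA"], row["mRNA"], int(row["module"]),
            frozenset(str(row["shared_miRNA_ids"]).split(";")),
            int(row["t"]), int(row["n"]), int(row["M"]), int(row["N"]),
            float(row["p"]), float(row["p_adj"]),
        )
        for _, row in df.iterrows()
    ]
    return CeRNANetwork(edges)


def stage_rwrm(cfg: RunConfig) -> dict:
    net = _aggregated_network_from_file(cfg)
    if not net.edges:
        raise ValueError("aggregated ceRNA network is empty; nothing to prioritize")
    layer2 = io.read_edges_tsv(_require(cfg, "layer2_edges.tsv", "simulate"))
    seeds = io.read_gene_list(_require(cfg, "seed_genes.txt", "simulate"))
    biotypes = io.read_biotypes_tsv(_require(cfg, "biotypes.tsv", "simulate")).to_dict()
    nodes = net.nodes()
    node_set = set(nodes)
    l1_edges = [(e.lncrna, e.mrna) for e in net.edges]
    l2_edges = [
        (r["gene_a"], r["gene_b"])
        for _, r in layer2.iterrows()
        if r["gene_a"] in node_set and r["gene_b"] in node_set
    ]
    graph = MultiplexGraph.from_edge_lists(nodes, [l1_edges, l2_edges])
    if l2_edges:
        tau = layer_weights(len(l1_edges) / len(l2_edges))
    else:
        log.warning("no second-layer edge survives restriction; uniform tau")
        tau = None
    params = RWRMParams(
        delta=cfg.delta, r=cfg.r, tau=tau,
        tolerance=cfg.rwr_tolerance, max_iter=cfg.rwr_max_iter,
    )
    log.info("rwrm: n=%d, layer edges %d/%d, delta=%.2f r=%.2f",
             len(nodes), len(l1_edges), len(l2_edges), cfg.delta, cfg.r)
    result = rwrm_scores(graph, seeds, params)
    table = result.to_frame(biotypes)
    table.to_csv(cfg.path("rwrm_scores.tsv"), sep="\t", index=False)
    top = prioritize_lncrnas(result, biotypes, top_k=cfg.top_lncrnas)
    io.write_json(
        {"top_lncrnas": [{"lncrna": g, "score": s} for g, s in top]},
        cfg.path("top_lncrnas.json"),
    )
    return {
        "n_nodes": len(nodes),
        "n_seeds_in_network": len(result.seeds),
        "tau": None if tau is None else [float(t) for t in tau],
        "n_iterations": result.n_iter,
        "top_lncrnas": [{"lncrna": g, "score": s} for g, s in top],
    }


def stage_pathways(cfg: RunConfig) -> dict:
    expr = io.read_expression_tsv(_require(cfg, "cleaned_expression.tsv", "preprocess"))
    phen = io.read_phenotype_tsv(_require(cfg, "phenotypes.tsv", "simulate")).loc[expr.columns]
    top = io.read_json(_require(cfg, "top_lncrnas.json", "rwrm"))["top_lncrnas"]
    sets = GeneSetCollection(io.read_gmt(_require(cfg, "gene_sets.gmt", "simulate")))
    sets = filter_gene_sets(
        sets, universe=expr.index, min_size=cfg.gmt_min_size, max_size=cfg.gmt_max_size
    )
    summary: dict = {"n_gene_sets": len(sets), "top_positive": {}}
    for entry in top:
        lnc = entry["lncrna"]
        table = pathway_association(expr, sets, phen, lnc, cfg.rhythm_coding)
        io.write_edges_tsv(table, cfg.path(f"pathway_assoc_{lnc}.tsv"))
        pos = table[table["coefficient"] > 0].head(10)
        summary["top_positive"][lnc] = pos[["set", "coefficient", "p"]].to_dict(
            orient="records"
        )
    io.write_json(summary, cfg.path("pathways_top.json"))
    return {"n_gene_sets": len(sets), "lncrnas": [e["lncrna"] for e in top]}


def stage_classify(cfg: RunConfig) -> dict:
    expr = io.read_expression_tsv(_require(cfg, "cleaned_expression.tsv", "preprocess"))
    phen = io.read_phenotype_tsv(_require(cfg, "phenotypes.tsv", "simulate")).loc[expr.columns]
    test_expr = io.read_expression_tsv(_require(cfg, "test_expression.tsv", "simulate"))
    test_phen = io.read_phenotype_tsv(_require(cfg, "test_phenotypes.tsv", "simulate"))
    net = _aggregated_network_from_file(cfg)
    top = io.read_json(_require(cfg, "top_lncrnas.json", "rwrm"))["top_lncrnas"]
    # training restricted to the extreme rhythm groups (AF/AF vs SR/SR)
    train_mask = phen["rhythm"].isin(["AF/AF", "SR/SR"])
    train_expr = expr.loc[:, train_mask.to_numpy()]
    train_labels = (phen.loc[train_mask, "rhythm"] == "AF/AF").astype(int)
    train_batches = phen.loc[train_mask, "batch"]
    test_labels = (test_phen["rhythm"] == "AF/AF").astype(int)
    seed = stage_seed(cfg.rng_seed, "classify")
    reports = {}
    for entry in top:
        lnc = entry["lncrna"]
        features = extract_pair_features(net, lnc)
        features = [g for g in features if g in expr.index and g in test_expr.index]
        per_lnc = {}
        for flag in (True, False):
            rep = build_classifier_report(
                lnc, features, train_expr, train_labels, test_expr, test_labels,
                train_batches=train_batches, remove_batch=flag,
                k=cfg.cv_folds, seed=seed,
            )
            per_lnc["batch_removed" if flag else "batch_retained"] = rep.to_dict()
        reports[lnc] = per_lnc
    io.write_json(reports, cfg.path("classifier_report.json"))
    return {
        lnc: {
            "cv_auc": rep["batch_removed"]["cv_auc"],
            "test_auc": rep["batch_removed"]["test_auc"],
            "test_auc_batch_retained": rep["batch_retained"]["test_auc"],
        }
        for lnc, rep in reports.items()
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "modules": stage_modules,
    "cerna": stage_cerna,
    "rwrm": stage_rwrm,
    "pathways": stage_pathways,
    "classify": stage_classify,
}


def run_stage(cfg: RunConfig, stage: str) -> dict:
    cfg.validate()
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage: {stage}")
    return _STAGE_FUNCS[stage](cfg)


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every stage in order and write the run report."""
    from . import __version__

    cfg.validate()
    t0 = time.perf_counter()
    stages: dict = {}
    order = STAGES if cfg.simulate else STAGES[1:]
    for stage in order:
        log.info("=== stage %s ===", stage)
        try:
            stages[stage] = _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    report = RunReport(
        config=cfg.to_dict(),
        version=__version__,
        stages=stages,
        wall_time_s=round(time.perf_counter() - t0, 3),
    )
    io.write_json(report.to_dict(), cfg.path("report.json"))
    return report
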