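"""Pipeline orchestration: configuration, staged runs, and the run manifest.

The stages mirror the analysis order of the study the pipeline reproduces:
consolidate DE-miRNA reports → select brain-expressed strong-evidence targets
→ build the four regulatory networks and rank hubs → pathway
over-representation → hub-gene expression heatmaps.  Each stage reads its
inputs from files (including earlier stages' outputs), writes only its own
outputs, and the composed stages are byte-identical to ``run_all``.  All
floats are serialized with 9 significant digits and rows sorted, so a fixed
config and seed reproduce every artifact exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import extract_submatrix, hierarchical_cluster, write_clustered
from .curation import (
    SUMMARY_VARIABLES,
    cohort_summary,
    consolidate_de_sets,
    load_de_reports,
    load_study_table,
)
from .enrichment import (
    load_gmt,
    run_ora,
    write_dot_plot_table,
    write_enrichment_table,
)
from .network import (
    build_network,
    centrality_table,
    network_summary,
    rank_hubs,
    write_centrality_table,
    write_graphml,
    write_sif,
)
from .targets import (
    BRAIN_TISSUES,
    brain_expression_filter,
    derive_target_sets,
    filter_interactions,
    intersect_sets,
    load_expression,
    load_interactions,
)

logger = logging.getLogger(__name__)

SET_NAMES = ("up", "down", "sn", "putamen")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults follow the source analysis
    (strong evidence only, TPM > 1 in all 13 brain tissues, top-30 pathways,
    hub tables at k = 5, 15, 20)."""

    de_reports: str | None = None
    studies: str | None = None
    interactions: str | None = None
    expression: str | None = None
    gmt: str | None = None
    ground_truth: str | None = None
    evidence_level: str = "strong"
    tpm_threshold: float = 1.0
    tissues: list[str] = field(default_factory=lambda: list(BRAIN_TISSUES))
    hub_k: list[int] = field(default_factory=lambda: [5, 15, 20])
    top_n_pathways: int = 30
    enrichment_method: str = "bh"
    universe_mode: str = "expressed"  # "expressed" or "collection"
    closeness_within_component: bool = False
    distance: str = "euclidean"
    linkage: str = "complete"
    scale_rows: bool = False
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise ValueError(f"config is missing the {what} input path")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} input not found: {p}")
    return p


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_curate(cfg: PipelineConfig) -> list[Path]:
    """Consolidate DE reports into the four sets; summarize the cohort."""
    out = _outdir(cfg)
    reports = load_de_reports(_require(cfg.de_reports, "DE-report"))
    sets = consolidate_de_sets(reports)
    written = []

    p = out / "consolidated_sets.tsv"
    with open(p, "w") as fh:
        fh.write("set_name\tmirna_id\n")
        for name in (*SET_NAMES, "conflicts", "multi_study"):
            for m in sorted(getattr(sets, name)):
                fh.write(f"{name}\t{m}\n")
    written.append(p)

    if cfg.studies is not None:
        records = load_study_table(_require(cfg.studies, "study-table"))
        p = out / "cohort_summary.tsv"
        with open(p, "w") as fh:
            fh.write("variable\tmedian\tq1\tq3\tn_nonmissing\n")
            for var in SUMMARY_VARIABLES:
                try:
                    s = cohort_summary(records, var)
                except ValueError:
                    continue
                fh.write(
                    f"{var}\t{s.median:.9g}\t{s.q1:.9g}\t{s.q3:.9g}\t{s.n_nonmissing}\n"
                )
        written.append(p)
    return written


def _load_consolidated(out: Path) -> dict[str, frozenset[str]]:
    p = out / "consolidated_sets.tsv"
    if not p.exists():
        raise FileNotFoundError(f"run the curate stage first: {p} not found")
    df = pd.read_csv(p, sep="\t", dtype=str)
    return {
        name: frozenset(df.loc[df["set_name"] == name, "mirna_id"])
        for name in SET_NAMES
    }


def stage_targets(cfg: PipelineConfig) -> list[Path]:
    """Derive the four target-gene sets and their intersection report."""
    out = _outdir(cfg)
    from .curation import ConsolidatedDESets

    sets_d = _load_consolidated(out)
    desets = ConsolidatedDESets(
        up=sets_d["up"],
        down=sets_d["down"],
        sn=sets_d["sn"],
        putamen=sets_d["putamen"],
        conflicts=sets_d["up"] & sets_d["down"],
        multi_study=frozenset(),
    )
    interactions = load_interactions(_require(cfg.interactions, "interaction"))
    expr = load_expression(_require(cfg.expression, "expression"))
    tsets = derive_target_sets(
        desets,
        interactions,
        expr,
        threshold=cfg.tpm_threshold,
        tissues=cfg.tissues,
        evidence=cfg.evidence_level,
    )
    written = []

    p = out / "target_sets.tsv"
    with open(p, "w") as fh:
        fh.write("set_name\tgene\n")
        for name, genes in tsets.as_dict().items():
            for g in sorted(genes):
                fh.write(f"{name}\t{g}\n")
    written.append(p)

    report = intersect_sets(tsets.as_dict())
    p = out / "intersection_report.tsv"
    with open(p, "w") as fh:
        fh.write("pattern\tcount\n")
        for pattern in sorted(report.bar_counts, key=lambda t: (-len(t), t)):
            fh.write(f"{'&'.join(pattern)}\t{report.bar_counts[pattern]}\n")
    written.append(p)

    p = out / "named_intersections.tsv"
    with open(p, "w") as fh:
        fh.write("sets\tgenes\n")
        names = list(report.set_names)
        combos = [tuple(names)] + [
            (a, b) for i, a in enumerate(names) for b in names[i + 1 :]
        ]
        for combo in combos:
            genes = report.intersection(*combo)
            fh.write(f"{'&'.join(combo)}\t{','.join(sorted(genes))}\n")
    written.append(p)
    return written


def _gene_universe(cfg: PipelineConfig, interactions, expr) -> set[str]:
    strong = filter_interactions(interactions, cfg.evidence_level)
    return brain_expression_filter(
        {i.gene for i in strong}, expr, cfg.tpm_threshold, cfg.tissues
    )


def stage_network(cfg: PipelineConfig) -> list[Path]:
    """Build the four regulatory networks; export topology and hub tables."""
    out = _outdir(cfg)
    sets_d = _load_consolidated(out)
    interactions = load_interactions(_require(cfg.interactions, "interaction"))
    expr = load_expression(_require(cfg.expression, "expression"))
    strong = filter_interactions(interactions, cfg.evidence_level)
    universe = _gene_universe(cfg, interactions, expr)

    written = []
    summaries = []
    for name in SET_NAMES:
        net = build_network(sets_d[name], strong, universe, name=name)
        s = network_summary(net)
        summaries.append((name, s))
        p = out / f"network_{name}.sif"
        write_sif(net, p)
        written.append(p)
        p = out / f"network_{name}.graphml"
        write_graphml(net, p)
        written.append(p)
        table = centrality_table(net)
        p = out / f"centrality_{name}.tsv"
        write_centrality_table(table, p)
        written.append(p)
        if net.n_nodes:
            for measure in ("dc", "bc", "cc"):
                for k in cfg.hub_k:
                    hubs = rank_hubs(table, measure, k)
                    p = out / f"hubs_{name}_{measure}_k{k}.tsv"
                    with open(p, "w") as fh:
                        fh.write("rank\tnode_id\tvalue\n")
                        for rank, (node, value) in enumerate(hubs.ranked, 1):
                            fh.write(f"{rank}\t{node}\t{value:.9g}\n")
                    written.append(p)

    p = out / "network_summaries.tsv"
    with open(p, "w") as fh:
        fh.write("network\tn_nodes\tn_edges\tn_components\tn_mirna\tn_gene\n")
        for name, s in summaries:
            fh.write(
                f"{name}\t{s.n_nodes}\t{s.n_edges}\t{s.n_components}"
                f"\t{s.n_mirna}\t{s.n_gene}\n"
            )
    written.append(p)
    return written


def _load_target_sets(out: Path) -> dict[str, frozenset[str]]:
    p = out / "target_sets.tsv"
    if not p.exists():
        raise FileNotFoundError(f"run the targets stage first: {p} not found")
    df = pd.read_csv(p, sep="\t", dtype=str)
    return {
        name: frozenset(df.loc[df["set_name"] == name, "gene"])
        for name in SET_NAMES
    }


def stage_enrich(cfg: PipelineConfig) -> list[Path]:
    """Pathway over-representation of each target-gene set."""
    out = _outdir(cfg)
    tsets = _load_target_sets(out)
    collection = load_gmt(_require(cfg.gmt, "GMT"))
    if cfg.universe_mode == "collection":
        universe = set(collection.all_genes)
    elif cfg.universe_mode == "expressed":
        expr = load_expression(_require(cfg.expression, "expression"))
        expressed = brain_expression_filter(
            collection.all_genes, expr, cfg.tpm_threshold, cfg.tissues
        )
        universe = set(collection.all_genes) & expressed
    else:
        raise ValueError(f"unknown universe_mode {cfg.universe_mode!r}")

    written = []
    for name in SET_NAMES:
        query = tsets[name] & universe
        p = out / f"enrichment_{name}.tsv"
        if not query:
            logger.warning("target set %r empty after restriction; skipping", name)
            p.write_text(
                "pathway_id\tdescription\tk\tK\tn\tN\tp_value\tq_value\toverlap_genes\n"
            )
            written.append(p)
            continue
        results = run_ora(query, collection, universe, method=cfg.enrichment_method)
        write_enrichment_table(results, p)
        written.append(p)
        p = out / f"top_pathways_{name}.tsv"
        write_dot_plot_table(results, p, n=cfg.top_n_pathways)
        written.append(p)
    return written


def stage_heatmap(cfg: PipelineConfig) -> list[Path]:
    """Cluster each network's top-degree hub genes across the brain tissues."""
    out = _outdir(cfg)
    expr = load_expression(_require(cfg.expression, "expression"))
    k = max(cfg.hub_k)
    written = []
    attempted = 0
    for name in SET_NAMES:
        hub_file = out / f"hubs_{name}_dc_k{k}.tsv"
        if not hub_file.exists():
            logger.warning("no hub table for network %r; skipping heatmap", name)
            continue
        hubs = pd.read_csv(hub_file, sep="\t", dtype=str)
        genes = [n for n in hubs["node_id"] if n in expr.frame.index]
        attempted += 1
        if len(genes) < 2:
            logger.warning("network %r has %d clusterable hub gene(s); skipping", name, len(genes))
            continue
        sub = extract_submatrix(expr, genes, cfg.tissues, allow_missing=True)
        cm = hierarchical_cluster(
            sub.matrix,
            distance=cfg.distance,
            linkage=cfg.linkage,
            scale_rows=cfg.scale_rows,
        )
        written.extend(write_clustered(cm, out / f"heatmap_{name}"))
    if attempted and not written:
        raise ValueError(
            "no network yielded a clusterable hub-gene matrix (need >= 2 genes)"
        )
    return written


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write the run manifest.

    Returns the manifest dict.  Any stage exception propagates after the
    completed stages' outputs are retained on disk.
    """
    out = _outdir(cfg)
    stage_outputs: dict[str, list[str]] = {}
    stages = [
        ("curate", stage_curate),
        ("targets", stage_targets),
        ("network", stage_network),
        ("enrich", stage_enrich),
        ("heatmap", stage_heatmap),
    ]
    for stage_name, fn in stages:
        logger.info("[%s] running", stage_name)
        stage_outputs[stage_name] = [str(p) for p in fn(cfg)]

    manifest: dict = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": stage_outputs,
    }

    # record the top-degree hub of each network, and planted-hub recovery
    # when the inputs came with a ground-truth file
    top_hubs = {}
    k = max(cfg.hub_k)
    for name in SET_NAMES:
        hub_file = out / f"hubs_{name}_dc_k{k}.tsv"
        if hub_file.exists():
            df = pd.read_csv(hub_file, sep="\t", dtype=str)
            top_hubs[name] = df["node_id"].iloc[0] if len(df) else None
    manifest["top_hub_dc"] = top_hubs
    if cfg.ground_truth is not None:
        truth = json.loads(Path(cfg.ground_truth).read_text())
        planted = truth.get("planted_hub_gene")
        manifest["planted_hub_gene"] = planted
        manifest["planted_hub_recovered"] = planted is not None and planted in set(
            top_hubs.values()
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def verify_manifest(out_dir: str | Path) -> bool:
    """Check that the manifest's config hash matches its embedded config."""
    manifest = json.loads((Path(out_dir) / "manifest.json").read_text())
    cfg = PipelineConfig.from_dict(manifest["config"])
    return cfg.config_hash() == manifest["config_hash"]
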