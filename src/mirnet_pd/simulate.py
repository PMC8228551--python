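"""Synthetic pipeline inputs with planted, recorded ground truth.

Every stage of the pipeline can be exercised without external downloads:

* an interaction table with strong/weak evidence labels and one planted hub
  gene whose connection probability is boosted;
* a genes × 13-brain-tissue median-TPM matrix in which a chosen fraction of
  genes is expressed strictly above TPM = 1 everywhere by construction and
  the rest fall below 1 in every tissue;
* a GMT collection with one pathway planted to overlap the query far above
  background (or an exact uniform null when no signal is requested);
* multi-study DE-miRNA reports with controlled direction conflicts and
  region overlaps.

One integer seed drives a named, independent pseudorandom stream per
generator, so adding a generator never perturbs the others, and serialization
is canonical (sorted rows, fixed float format): the same seed yields
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .curation import ConsolidatedDESets, DEReport
from .enrichment import GeneSetCollection
from .targets import BRAIN_TISSUES, ExpressionMatrix, Interaction

import pandas as pd

#: stream ids keep the per-generator RNGs independent under one seed
_STREAMS = {
    "interactions": 1,
    "expression": 2,
    "pathways": 3,
    "de_reports": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class GroundTruth:
    """What the generators planted, for end-to-end recovery checks."""

    seed: int
    planted_hub_gene: str | None = None
    planted_pathway_id: str | None = None
    brain_expressed_genes: frozenset[str] = frozenset()
    strong_edge_count: int = 0
    n_edges: int = 0
    de_sets_truth: ConsolidatedDESets | None = None

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "planted_hub_gene": self.planted_hub_gene,
            "planted_pathway_id": self.planted_pathway_id,
            "brain_expressed_genes": sorted(self.brain_expressed_genes),
            "strong_edge_count": self.strong_edge_count,
            "n_edges": self.n_edges,
        }
        if self.de_sets_truth is not None:
            d["de_sets_truth"] = {
                name: sorted(getattr(self.de_sets_truth, name))
                for name in ("up", "down", "sn", "putamen", "conflicts", "multi_study")
            }
        return json.dumps(d, indent=2, sort_keys=True)


def _mirna_names(n: int, prefix: str = "hsa-mir-sim") -> list[str]:
    return [f"{prefix}-{i + 1:03d}" for i in range(n)]


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def simulate_interactions(
    n_mirna: int = 20,
    n_gene: int = 50,
    density: float = 0.1,
    strong_fraction: float = 0.7,
    hub_boost: float = 10.0,
    seed: int = 0,
) -> tuple[list[Interaction], GroundTruth]:
    """Bernoulli bipartite interaction table with one planted hub gene.

    Every (miRNA, gene) pair is an edge with probability ``density``, except
    the planted hub gene whose probability is ``min(1, density * hub_boost)``;
    each edge is labelled strong independently with probability
    ``strong_fraction``.
    """
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must be in [0, 1]")
    if not (0.0 <= strong_fraction <= 1.0):
        raise ValueError("strong_fraction must be in [0, 1]")
    if hub_boost < 1.0:
        raise ValueError("hub_boost must be >= 1")
    rng = _rng(seed, "interactions")
    mirnas = _mirna_names(n_mirna)
    genes = _gene_names(n_gene)
    hub = genes[int(rng.integers(n_gene))] if n_gene else None

    interactions: list[Interaction] = []
    strong_count = 0
    for m in mirnas:
        for g in genes:
            p = min(1.0, density * hub_boost) if g == hub else density
            if rng.random() < p:
                evidence = "strong" if rng.random() < strong_fraction else "weak"
                strong_count += evidence == "strong"
                interactions.append(Interaction(m, g, evidence, source="synthetic"))
    truth = GroundTruth(
        seed=seed,
        planted_hub_gene=hub,
        strong_edge_count=strong_count,
        n_edges=len(interactions),
    )
    return interactions, truth


def simulate_expression(
    genes: Sequence[str],
    tissues: Sequence[str] = BRAIN_TISSUES,
    expressed_fraction: float = 0.6,
    expressed_genes: Sequence[str] | None = None,
    lognormal_mu: float = 2.0,
    lognormal_sigma: float = 1.0,
    unexpressed_tpm_max: float = 0.9,
    seed: int = 0,
) -> tuple[ExpressionMatrix, frozenset[str]]:
    """Median-TPM matrix with a planted brain-expressed gene subset.

    Expressed genes draw ``1 + Lognormal(mu, sigma)`` in every tissue, hence
    are strictly above the TPM = 1 filter by construction; the rest draw
    ``Uniform(0, unexpressed_tpm_max)`` everywhere and always fail it.  The
    expressed subset is ``round(expressed_fraction * len(genes))`` genes
    chosen at random, unless pinned explicitly via ``expressed_genes``.
    Returns the matrix and the planted expressed set.
    """
    if not (0.0 <= expressed_fraction <= 1.0):
        raise ValueError("expressed_fraction must be in [0, 1]")
    if not (0.0 < unexpressed_tpm_max < 1.0):
        raise ValueError("unexpressed_tpm_max must be in (0, 1)")
    rng = _rng(seed, "expression")
    genes = list(genes)
    if expressed_genes is None:
        n_expr = round(expressed_fraction * len(genes))
        expressed = frozenset(rng.choice(genes, size=n_expr, replace=False))
    else:
        expressed = frozenset(expressed_genes)
        if not expressed <= set(genes):
            raise ValueError("expressed_genes must be a subset of genes")

    data = np.empty((len(genes), len(tissues)))
    for i, g in enumerate(genes):
        if g in expressed:
            data[i] = 1.0 + rng.lognormal(lognormal_mu, lognormal_sigma, len(tissues))
        else:
            data[i] = rng.uniform(0.0, unexpressed_tpm_max, len(tissues))
    df = pd.DataFrame(data, index=genes, columns=list(tissues))
    return ExpressionMatrix(df), expressed


def simulate_pathways(
    universe: Sequence[str],
    n_pathways: int = 30,
    size_range: tuple[int, int] = (10, 80),
    planted_overlap_rate: float = 0.5,
    background_rate: float = 0.1,
    query_size: int = 50,
    seed: int = 0,
) -> tuple[GeneSetCollection, frozenset[str], GroundTruth]:
    """GMT collection with one planted over-represented pathway.

    With ``planted_overlap_rate > background_rate`` one pathway draws
    ``round(size * planted_overlap_rate)`` members from the query and the
    background pathways ``round(size * background_rate)``; with the two
    rates equal all pathways are uniform samples from the universe (an exact
    hypergeometric null) and no pathway is planted.
    """
    for rate in (planted_overlap_rate, background_rate):
        if not (0.0 < rate < 1.0):
            raise ValueError("overlap rates must be in (0, 1)")
    if planted_overlap_rate < background_rate:
        raise ValueError("planted_overlap_rate must be >= background_rate")
    universe = sorted(set(universe))
    if query_size > len(universe):
        raise ValueError("query_size exceeds universe size")
    rng = _rng(seed, "pathways")
    query = frozenset(rng.choice(universe, size=query_size, replace=False))
    non_query = sorted(set(universe) - query)

    null = planted_overlap_rate == background_rate
    planted_idx = None if null else int(rng.integers(n_pathways))
    pathways = []
    for j in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        pid = f"PW{j + 1:03d}"
        if null:
            members = rng.choice(universe, size=size, replace=False)
        else:
            rate = planted_overlap_rate if j == planted_idx else background_rate
            k = min(round(size * rate), len(query), size)
            from_query = rng.choice(sorted(query), size=k, replace=False)
            from_rest = rng.choice(non_query, size=min(size - k, len(non_query)), replace=False)
            members = np.concatenate([from_query, from_rest])
        pathways.append((pid, f"synthetic pathway {j + 1}", frozenset(members)))

    truth = GroundTruth(
        seed=seed,
        planted_pathway_id=None if null else f"PW{planted_idx + 1:03d}",
    )
    return GeneSetCollection(pathways=tuple(pathways)), query, truth


def simulate_de_reports(
    n_studies: int = 4,
    n_up: int = 12,
    n_down: int = 8,
    n_conflicts: int = 1,
    n_sn: int = 6,
    n_putamen: int = 4,
    n_shared_sn_putamen: int = 2,
    n_multi_study: int = 3,
    seed: int = 0,
    mirna_pool: Sequence[str] | None = None,
) -> tuple[list[DEReport], ConsolidatedDESets]:
    """Per-study DE reports whose consolidation is known exactly.

    ``n_up``/``n_down`` count the direction sets *including* the
    ``n_conflicts`` miRNAs planted in both; ``n_shared_sn_putamen`` of the
    region members are planted in both substantia nigra and putamen.
    Multi-study miRNAs are attributed to two distinct studies.  By default
    miRNA identifiers are invented; passing ``mirna_pool`` draws them from an
    existing universe instead (e.g. the miRNAs of a simulated interaction
    table), so downstream stages can join the two files.
    """
    if n_conflicts > min(n_up, n_down):
        raise ValueError("n_conflicts exceeds a direction set")
    if n_shared_sn_putamen > min(n_sn, n_putamen):
        raise ValueError("n_shared_sn_putamen exceeds a region set")
    if n_sn + n_putamen - n_shared_sn_putamen > n_up + n_down - n_conflicts:
        raise ValueError("region sets exceed the miRNA universe")
    if n_multi_study > n_up + n_down - n_conflicts:
        raise ValueError("n_multi_study exceeds the miRNA universe")
    if n_studies < 2 and (n_multi_study or n_conflicts):
        raise ValueError("conflicts/multi-study need at least 2 studies")

    rng = _rng(seed, "de_reports")
    n_distinct = n_up + n_down - n_conflicts
    if mirna_pool is not None:
        if len(mirna_pool) < n_distinct:
            raise ValueError("mirna_pool smaller than the requested universe")
        pool = list(mirna_pool)
        conflicts = pool[:n_conflicts]
        up_only = pool[n_conflicts:n_up]
        down_only = pool[n_up:n_distinct]
    else:
        conflicts = _mirna_names(n_conflicts, "hsa-mir-simc")
        up_only = _mirna_names(n_up - n_conflicts, "hsa-mir-simu")
        down_only = _mirna_names(n_down - n_conflicts, "hsa-mir-simd")
    up = frozenset(up_only) | frozenset(conflicts)
    down = frozenset(down_only) | frozenset(conflicts)
    universe = sorted(up | down)

    members = list(rng.permutation(universe))
    shared = members[:n_shared_sn_putamen]
    sn = frozenset(members[:n_sn])
    putamen = frozenset(shared + members[n_sn : n_sn + n_putamen - n_shared_sn_putamen])
    multi = frozenset(rng.choice(universe, size=n_multi_study, replace=False))

    studies = [f"sim-s{i + 1}" for i in range(n_studies)]
    reports: list[DEReport] = []
    for m in universe:
        regions = []
        if m in sn:
            regions.append("substantia_nigra")
        if m in putamen:
            regions.append("putamen")
        if not regions:
            regions = ["other"]
        directions = [d for d, s in (("up", up), ("down", down)) if m in s]
        primary = studies[int(rng.integers(n_studies))]
        assigned = [primary]
        if m in multi or len(directions) > 1:
            second = studies[(studies.index(primary) + 1) % n_studies]
            assigned.append(second)
        for i, d in enumerate(directions):
            sid = assigned[min(i, len(assigned) - 1)]
            for r in regions:
                reports.append(DEReport(sid, m, r, d))
        if m in multi and len(directions) == 1:
            for r in regions:
                reports.append(DEReport(assigned[1], m, r, directions[0]))

    truth = ConsolidatedDESets(
        up=up,
        down=down,
        sn=sn,
        putamen=putamen,
        conflicts=frozenset(conflicts),
        multi_study=multi | frozenset(conflicts),
    )
    return reports, truth


def write_de_reports(reports: Sequence[DEReport], path: str | Path) -> None:
    """Canonical serialization: sorted rows."""
    rows = sorted((r.study_id, r.mirna_id, r.region, r.direction) for r in reports)
    with open(path, "w") as fh:
        fh.write("study_id\tmirna_id\tregion\tdirection\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


@dataclass
class SyntheticScenario:
    """A coordinated planted instance covering every pipeline stage."""

    interactions: list[Interaction]
    expression: ExpressionMatrix
    collection: GeneSetCollection
    query: frozenset[str]
    de_reports: list[DEReport]
    truth: GroundTruth


def simulate_scenario(
    seed: int,
    n_mirna: int = 20,
    n_gene: int = 50,
    density: float = 0.1,
    strong_fraction: float = 0.7,
    hub_boost: float = 10.0,
    expressed_fraction: float = 0.6,
    n_pathways: int = 30,
    pathway_universe_size: int = 2000,
    query_size: int = 50,
    planted_overlap_rate: float = 0.5,
    background_rate: float = 0.1,
) -> SyntheticScenario:
    """One coherent planted instance for end-to-end recovery runs.

    The planted hub gene is forced into the brain-expressed subset so that
    the expression filter cannot remove it, and the pathway universe embeds
    the interaction genes.
    """
    interactions, truth = simulate_interactions(
        n_mirna, n_gene, density, strong_fraction, hub_boost, seed
    )
    genes = _gene_names(n_gene)
    rng = _rng(seed, "expression")
    n_expr = round(expressed_fraction * n_gene)
    others = [g for g in genes if g != truth.planted_hub_gene]
    chosen = list(rng.choice(others, size=max(0, n_expr - 1), replace=False))
    expressed = frozenset(chosen + [truth.planted_hub_gene])
    expression, expressed = simulate_expression(
        genes, expressed_genes=sorted(expressed), seed=seed
    )
    universe = genes + _gene_names(pathway_universe_size)[n_gene:]
    collection, query, ptruth = simulate_pathways(
        universe,
        n_pathways=n_pathways,
        planted_overlap_rate=planted_overlap_rate,
        background_rate=background_rate,
        query_size=query_size,
        seed=seed,
    )
    de_reports, de_truth = simulate_de_reports(
        seed=seed, mirna_pool=_mirna_names(n_mirna)
    )
    truth.brain_expressed_genes = expressed
    truth.planted_pathway_id = ptruth.planted_pathway_id
    truth.de_sets_truth = de_truth
    return SyntheticScenario(
        interactions=interactions,
        expression=expression,
        collection=collection,
        query=query,
        de_reports=de_reports,
        truth=truth,
    )
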