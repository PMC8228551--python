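"""Target-gene selection: evidence filtering and brain-expression filtering.

Predicted miRNA targets arrive as an evidence-labelled interaction table
(miRNA, gene symbol, strong/weak validation).  Only strongly validated edges
are kept, and target genes are restricted to those expressed above a TPM
threshold in *every* brain tissue of a GTEx-style median-TPM matrix.  The
surviving targets of each DE-miRNA set form the four target-gene sets, whose
disjoint membership patterns (UpSet-style) are reported here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import ConsolidatedDESets, normalize_mirna_id

logger = logging.getLogger(__name__)

EVIDENCE_LEVELS = ("strong", "weak")

#: the 13 GTEx brain tissues used for the expression filter
BRAIN_TISSUES = (
    "amygdala",
    "anterior_cingulate_cortex",
    "caudate_basal_ganglia",
    "cerebellar_hemisphere",
    "cerebellum",
    "cortex",
    "frontal_cortex",
    "hippocampus",
    "hypothalamus",
    "nucleus_accumbens_basal_ganglia",
    "putamen",
    "spinal_cord",
    "substantia_nigra",
)

#: default mapping from interaction-table evidence dialects to the
#: strong/weak dichotomy (miRTarBase-style labels included)
DEFAULT_EVIDENCE_MAP = {
    "strong": "strong",
    "weak": "weak",
    "functional mti": "strong",
    "functional mti (weak)": "weak",
}


@dataclass(frozen=True)
class Interaction:
    """One validated miRNA→gene edge with its evidence level."""

    mirna_id: str
    gene: str
    evidence: str
    source: str | None = None

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"invalid evidence level {self.evidence!r}")
        if not self.gene:
            raise ValueError("empty gene symbol")


class ExpressionMatrix:
    """Genes × tissues matrix of median TPM values.

    Thin wrapper over a pandas DataFrame (index = gene symbols, columns =
    tissue labels) enforcing uniqueness and non-negativity.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate tissue labels")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if (values < 0).any():
            raise ValueError("negative TPM values")
        self._df = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def tissues(self) -> list[str]:
        return list(self._df.columns)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def __contains__(self, gene: str) -> bool:
        return gene in self._df.index

    def __getitem__(self, key: tuple[str, str]) -> float:
        gene, tissue = key
        return float(self._df.at[gene, tissue])


def load_interactions(
    path: str | Path,
    evidence_map: Mapping[str, str] | None = None,
) -> list[Interaction]:
    """Load an interaction TSV (mirna_id, gene, evidence[, source]).

    ``evidence_map`` translates dialect labels (case-insensitive) to
    strong/weak; unmapped labels raise.
    """
    emap = {k.lower(): v for k, v in (evidence_map or DEFAULT_EVIDENCE_MAP).items()}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["mirna_id", "gene", "evidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    out = []
    for i, row in df.iterrows():
        label = row["evidence"].strip().lower()
        if label not in emap:
            raise ValueError(
                f"unknown evidence label {row['evidence']!r} in row {int(i) + 2}"
            )
        out.append(
            Interaction(
                mirna_id=normalize_mirna_id(row["mirna_id"]),
                gene=row["gene"].strip().upper(),
                evidence=emap[label],
                source=(row["source"].strip() or None) if "source" in df.columns else None,
            )
        )
    return out


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    """Canonical serialization: sorted rows, stable column order."""
    rows = sorted(
        (i.mirna_id, i.gene, i.evidence, i.source or "") for i in interactions
    )
    df = pd.DataFrame(rows, columns=["mirna_id", "gene", "evidence", "source"])
    df.to_csv(path, sep="\t", index=False)


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Load a genes × tissues median-TPM TSV.

    Plain TSV: first column gene symbols, remaining columns tissue labels.
    GCT 1.2 is accepted too: its two header lines are skipped and the
    Description column dropped.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    df.index.name = None
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.frame.sort_index()
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.9g")


def filter_interactions(
    table: Sequence[Interaction], level: str = "strong"
) -> list[Interaction]:
    """Keep only interactions at the requested evidence level, collapsing
    duplicate (miRNA, gene) pairs to the first occurrence; order preserved."""
    if level not in EVIDENCE_LEVELS:
        raise ValueError(f"unknown evidence level {level!r}")
    seen: set[tuple[str, str]] = set()
    out = []
    for inter in table:
        if inter.evidence != level:
            continue
        key = (inter.mirna_id, inter.gene)
        if key in seen:
            continue
        seen.add(key)
        out.append(inter)
    return out


def classify_brain_expression(
    genes: Iterable[str],
    expr: ExpressionMatrix,
    threshold: float = 1.0,
    tissues: Sequence[str] | None = None,
) -> tuple[set[str], set[str], set[str]]:
    """Partition ``genes`` into (retained, below-threshold, absent-from-matrix).

    A gene is retained iff its TPM is strictly greater than ``threshold`` in
    every requested tissue.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    tissues = list(tissues) if tissues is not None else list(BRAIN_TISSUES)
    missing_tissues = [t for t in tissues if t not in expr.frame.columns]
    if missing_tissues:
        raise KeyError(f"tissues missing from expression matrix: {missing_tissues}")

    genes = set(genes)
    absent = {g for g in genes if g not in expr}
    present = sorted(genes - absent)
    if present:
        sub = expr.frame.loc[present, tissues].to_numpy(dtype=float)
        ok = (sub > threshold).all(axis=1)
        retained = {g for g, keep in zip(present, ok) if keep}
    else:
        retained = set()
    return retained, set(present) - retained, absent


def brain_expression_filter(
    genes: Iterable[str],
    expr: ExpressionMatrix,
    threshold: float = 1.0,
    tissues: Sequence[str] | None = None,
) -> set[str]:
    """Genes with median TPM strictly above ``threshold`` in all brain tissues.

    Genes absent from the matrix are excluded (and logged); a boundary gene
    with TPM exactly equal to the threshold in any tissue is excluded.
    """
    retained, _below, absent = classify_brain_expression(genes, expr, threshold, tissues)
    if absent:
        logger.warning(
            "%d gene(s) absent from the expression matrix were excluded: %s",
            len(absent),
            ", ".join(sorted(absent)[:10]),
        )
    return retained


@dataclass(frozen=True)
class TargetSets:
    """Expression-filtered target-gene sets of the four DE-miRNA sets."""

    up_targets: frozenset[str]
    down_targets: frozenset[str]
    sn_targets: frozenset[str]
    putamen_targets: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return (
            self.up_targets | self.down_targets | self.sn_targets | self.putamen_targets
        )

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "up": self.up_targets,
            "down": self.down_targets,
            "sn": self.sn_targets,
            "putamen": self.putamen_targets,
        }


def derive_target_sets(
    sets: ConsolidatedDESets,
    interactions: Sequence[Interaction],
    expr: ExpressionMatrix,
    threshold: float = 1.0,
    tissues: Sequence[str] | None = None,
    evidence: str = "strong",
) -> TargetSets:
    """Strong-evidence targets of each DE-miRNA set, restricted to the
    brain-expressed gene universe.

    An empty miRNA set yields an empty target set (logged, not an error).
    """
    strong = filter_interactions(interactions, evidence)
    all_genes = {i.gene for i in strong}
    universe = brain_expression_filter(all_genes, expr, threshold, tissues)

    def targets_of(mirnas: frozenset[str]) -> frozenset[str]:
        if not mirnas:
            logger.warning("empty miRNA set: target set is empty")
            return frozenset()
        return frozenset(
            i.gene for i in strong if i.mirna_id in mirnas and i.gene in universe
        )

    return TargetSets(
        up_targets=targets_of(sets.up),
        down_targets=targets_of(sets.down),
        sn_targets=targets_of(sets.sn),
        putamen_targets=targets_of(sets.putamen),
    )


@dataclass(frozen=True)
class IntersectionReport:
    """Disjoint membership patterns over named gene sets (UpSet-style).

    ``bar_counts`` maps each non-empty membership pattern — a sorted tuple of
    set names — to the number of genes showing exactly that pattern; the
    patterns partition the union of all sets.
    """

    set_names: tuple[str, ...]
    membership: pd.DataFrame  # genes × set_names boolean
    bar_counts: dict[tuple[str, ...], int]

    def intersection(self, *names: str) -> set[str]:
        """Plain intersection of the named sets (not the disjoint pattern)."""
        for n in names:
            if n not in self.set_names:
                raise KeyError(n)
        mask = self.membership[list(names)].all(axis=1)
        return set(self.membership.index[mask])

    @property
    def union_size(self) -> int:
        return len(self.membership)


def intersect_sets(
    named_sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> IntersectionReport:
    """Exact membership patterns and counts over >=2 named sets."""
    if isinstance(named_sets, Mapping):
        pairs = list(named_sets.items())
    else:
        pairs = list(named_sets)
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate set names in {names}")
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {n: set(s) for n, s in pairs}
    union = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {n: [g in sets[n] for g in union] for n in names}, index=union
    )
    bar_counts: dict[tuple[str, ...], int] = {}
    for _g, row in membership.iterrows():
        pattern = tuple(n for n in names if row[n])
        bar_counts[pattern] = bar_counts.get(pattern, 0) + 1
    return IntersectionReport(
        set_names=tuple(names), membership=membership, bar_counts=bar_counts
    )
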