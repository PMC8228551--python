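"""Pathway over-representation analysis (hypergeometric test + BH FDR).

A query gene set is tested against every pathway of a GMT collection: the
p-value is the hypergeometric upper tail P(X >= k) for drawing ``k`` pathway
members in a query of size ``n`` from a universe of ``N`` genes of which
``K`` belong to the pathway.  Benjamini–Hochberg step-up adjustment is
applied across all tested pathways (Bonferroni available by flag), and the
"most significant" ordering is ascending adjusted p with deterministic ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Pathways as (id, description, member genes) with unique ids."""

    pathways: tuple[tuple[str, str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pathway ids")
        for pid, _d, members in self.pathways:
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def members(self, pathway_id: str) -> frozenset[str]:
        for pid, _d, m in self.pathways:
            if pid == pathway_id:
                return m
        raise KeyError(pathway_id)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _pid, _d, m in self.pathways:
            out |= m
        return frozenset(out)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: id, description, members...).

    Duplicate members within a pathway are collapsed; a line with fewer than
    three fields is a parse error reported with its line number.
    """
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise ValueError(f"GMT line {lineno}: pathway {pid!r} has no members")
            pathways.append((pid, desc, frozenset(members)))
    return GeneSetCollection(pathways=tuple(pathways))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Canonical GMT serialization (members sorted)."""
    with open(path, "w") as fh:
        for pid, desc, members in collection.pathways:
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts pathway members (K of N in the universe) in a size-n query drawn
    without replacement.  Bounds are validated; k = 0 gives exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    overlap_genes: frozenset[str]


def run_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each pathway of ``collection``.

    Query genes and pathway members outside the universe are dropped (with a
    warning for the query); every pathway retaining at least one universe
    member is tested.  Results are sorted ascending by (q, p, pathway_id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(outside),
            ", ".join(sorted(outside)[:10]),
        )
    query &= universe
    if not query:
        raise ValueError("empty query after restriction to the universe")

    N = len(universe)
    n = len(query)
    tested = []
    pvals = []
    for pid, desc, members in collection.pathways:
        members_u = members & universe
        if not members_u:
            continue
        overlap = members_u & query
        p = hypergeometric_p(len(overlap), len(members_u), n, N)
        tested.append((pid, desc, overlap, len(members_u), p))
        pvals.append(p)

    if not tested:
        return []
    if method == "bh":
        qvals = multipletests(pvals, method="fdr_bh")[1]
    elif method == "bonferroni":
        qvals = multipletests(pvals, method="bonferroni")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")

    results = [
        EnrichmentResult(
            pathway_id=pid,
            description=desc,
            k=len(overlap),
            K=K,
            n=n,
            N=N,
            p_value=float(p),
            q_value=float(q),
            overlap_genes=frozenset(overlap),
        )
        for (pid, desc, overlap, K, p), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.pathway_id))
    return results


def top_pathways(results: Sequence[EnrichmentResult], n: int = 30) -> list[EnrichmentResult]:
    """The first min(n, len) results under the significance ordering."""
    ordered = sorted(results, key=lambda r: (r.q_value, r.p_value, r.pathway_id))
    return list(ordered[: max(0, n)])


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tdescription\tk\tK\tn\tN\tp_value\tq_value\toverlap_genes\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.description}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.9g}\t{r.q_value:.9g}\t{','.join(sorted(r.overlap_genes))}\n"
            )


def write_dot_plot_table(
    results: Sequence[EnrichmentResult], path: str | Path, n: int = 30
) -> None:
    """Dot-plot-ready table (pathway, overlap size, adjusted p) for the top-n
    pathways — circle size maps to the number of query genes in the pathway."""
    with open(path, "w") as fh:
        fh.write("pathway_id\tdescription\tk\tq_value\n")
        for r in top_pathways(results, n):
            fh.write(f"{r.pathway_id}\t{r.description}\t{r.k}\t{r.q_value:.9g}\n")
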