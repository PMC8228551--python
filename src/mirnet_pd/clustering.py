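"""Heatmap-ready hierarchical clustering of expression submatrices.

Hub-gene × brain-tissue TPM submatrices are clustered agglomeratively on
rows and columns independently (scipy linkage on euclidean or correlation
distances).  Leaf order is made fully deterministic: at every merge the
subtree containing the smaller original index is placed on the left, so the
output never depends on dictionary order or optimal-leaf-ordering heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _linkage
from scipy.spatial.distance import pdist

from .targets import ExpressionMatrix

logger = logging.getLogger(__name__)

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("complete", "average", "ward")


@dataclass(frozen=True)
class SubmatrixResult:
    matrix: ExpressionMatrix
    missing_genes: frozenset[str]
    missing_tissues: frozenset[str]


def extract_submatrix(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    tissues: Sequence[str],
    allow_missing: bool = False,
) -> SubmatrixResult:
    """Extract a genes × tissues submatrix in the requested order.

    Missing genes/tissues are reported in the result; unless
    ``allow_missing`` they raise.  If every requested gene is absent this is
    always an error.
    """
    missing_genes = frozenset(g for g in genes if g not in expr.frame.index)
    missing_tissues = frozenset(t for t in tissues if t not in expr.frame.columns)
    if len(missing_genes) == len(genes):
        raise KeyError(f"none of the requested genes are in the matrix: {sorted(genes)[:10]}")
    if (missing_genes or missing_tissues) and not allow_missing:
        raise KeyError(
            f"missing genes {sorted(missing_genes)} / tissues {sorted(missing_tissues)}"
        )
    if missing_genes or missing_tissues:
        logger.warning(
            "dropping %d missing gene(s), %d missing tissue(s)",
            len(missing_genes),
            len(missing_tissues),
        )
    keep_g = [g for g in genes if g not in missing_genes]
    keep_t = [t for t in tissues if t not in missing_tissues]
    return SubmatrixResult(
        matrix=ExpressionMatrix(expr.frame.loc[keep_g, keep_t]),
        missing_genes=missing_genes,
        missing_tissues=missing_tissues,
    )


@dataclass(frozen=True)
class ClusteredMatrix:
    """Row/column dendrogram orders and linkages for one matrix."""

    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    values: pd.DataFrame  # reordered
    row_linkage: np.ndarray  # scipy linkage matrix
    col_linkage: np.ndarray


def _leaf_order(link: np.ndarray, n_leaves: int) -> list[int]:
    """Deterministic dendrogram leaf order: the subtree whose minimum
    original index is smaller goes left at every merge."""
    if n_leaves == 1:
        return [0]
    leaves: dict[int, list[int]] = {i: [i] for i in range(n_leaves)}
    for step, (a, b, _h, _c) in enumerate(link):
        left, right = leaves.pop(int(a)), leaves.pop(int(b))
        if min(right) < min(left):
            left, right = right, left
        leaves[n_leaves + step] = left + right
    (order,) = leaves.values()
    return order


def _cluster_axis(data: np.ndarray, distance: str, method: str) -> np.ndarray:
    if data.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    if distance == "correlation" and np.any(np.std(data, axis=1) == 0):
        raise ValueError("correlation distance undefined for constant rows")
    d = pdist(data, metric=distance)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances; check the input matrix")
    return _linkage(d, method=method)


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    distance: str = "euclidean",
    linkage: str = "complete",
    scale_rows: bool = False,
) -> ClusteredMatrix:
    """Cluster rows and columns of an expression matrix independently.

    ``scale_rows`` z-scores each gene across tissues before computing
    distances (the reordered values returned are the scaled ones in that
    case).  Requires >= 2 rows and >= 2 columns and no missing values.
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    df = matrix.frame
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(f"matrix must be at least 2x2, got {df.shape}")
    data = df.to_numpy(dtype=float)
    if scale_rows:
        sd = data.std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot z-score constant rows")
        data = (data - data.mean(axis=1, keepdims=True)) / sd
        df = pd.DataFrame(data, index=df.index, columns=df.columns)

    row_link = _cluster_axis(data, distance, linkage)
    col_link = _cluster_axis(data.T, distance, linkage)
    row_idx = _leaf_order(row_link, data.shape[0])
    col_idx = _leaf_order(col_link, data.shape[1])
    row_order = tuple(df.index[i] for i in row_idx)
    col_order = tuple(df.columns[i] for i in col_idx)
    return ClusteredMatrix(
        row_order=row_order,
        col_order=col_order,
        values=df.loc[list(row_order), list(col_order)],
        row_linkage=row_link,
        col_linkage=col_link,
    )


def write_clustered(cm: ClusteredMatrix, prefix: str | Path) -> list[Path]:
    """Write the reordered matrix and both linkage tables as TSVs."""
    prefix = Path(prefix)
    out = []
    p = prefix.with_name(prefix.name + "_matrix.tsv")
    cm.values.to_csv(p, sep="\t", index_label="gene", float_format="%.9g")
    out.append(p)
    for which, link in (("row", cm.row_linkage), ("col", cm.col_linkage)):
        p = prefix.with_name(f"{prefix.name}_{which}_linkage.tsv")
        pd.DataFrame(
            link, columns=["cluster_a", "cluster_b", "height", "size"]
        ).to_csv(p, sep="\t", index=False, float_format="%.9g")
        out.append(p)
    return out


def plot_heatmap(cm: ClusteredMatrix, path: str | Path) -> None:
    """Optional PNG/SVG rendering of the clustered matrix (never required)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(cm.row_order))))
    im = ax.imshow(cm.values.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(cm.col_order)), cm.col_order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.row_order)), cm.row_order, fontsize=7)
    fig.colorbar(im, ax=ax, label="median TPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
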