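"""Hierarchical clustering of abundance / enrichment profiles.

Samples and families are clustered with agglomerative linkage on a
configurable distance (defaults: average linkage, Euclidean distance on the
profile values), and the dendrograms are serialised as Newick strings with
branch lengths so any tree viewer can re-draw them.  A display cap — the
percent value at which heatmap colours saturate — is applied to the exported
matrix values only, never to the distances.

To make results independent of input row order, labels on each clustered
axis are sorted lexicographically before distances are computed; scipy's
linkage is then deterministic, and equal-distance merges resolve by that
label order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiling import AbundanceProfile, FunctionCountMatrix

__all__ = ["ClusterResult", "cluster_profile", "export_heatmap"]


@dataclass
class ClusterResult:
    """Clustered matrix with leaf orders and serialized dendrograms."""

    matrix_values: pd.DataFrame   # reordered, cap applied if requested
    row_order: list[str]
    col_order: list[str]
    row_tree: str | None          # Newick with branch lengths, or None
    col_tree: str | None
    linkage_method: str
    distance_metric: str
    cap: float | None = None


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as Newick with branch lengths.

    Branch length of a node is its parent's merge height minus its own
    (leaves have height 0), so the tree path between two leaves equals twice
    their cophenetic merge height.
    """
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    if tree.is_leaf():
        return f"({labels[tree.id]}:0);"
    left = build(tree.left, tree.dist)
    right = build(tree.right, tree.dist)
    return f"({left},{right});"


def _cluster_axis(values: pd.DataFrame, method: str, metric: str):
    """Linkage over rows of `values`; returns (ordered labels, newick)."""
    labels = list(values.index)
    Z = hierarchy.linkage(pdist(values.to_numpy(), metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    ordered = [labels[i] for i in order]
    return ordered, _linkage_to_newick(Z, labels), Z


def cluster_profile(
    matrix: FunctionCountMatrix | AbundanceProfile | pd.DataFrame,
    axes: str = "both",
    linkage: str = "average",
    metric: str = "euclidean",
    cap: float | None = None,
) -> ClusterResult:
    """Cluster rows and/or columns of a profile for heatmap display.

    Parameters
    ----------
    matrix
        A count matrix, an abundance profile, or a plain DataFrame
        (rows = families/taxa, columns = samples).  Count matrices are
        column-normalised to percent before distances are computed, so
        samples of different depth are comparable.
    axes
        ``"rows"``, ``"cols"`` or ``"both"``.
    cap
        Optional saturation value applied to the exported matrix values
        (display only; distances always use uncapped values).
    """
    if axes not in ("rows", "cols", "both"):
        raise ValueError(f"unknown axes {axes!r}")
    if isinstance(matrix, FunctionCountMatrix):
        values = matrix.counts.div(matrix.sample_totals, axis=1) * 100.0
    elif isinstance(matrix, AbundanceProfile):
        values = matrix.values.copy()
    else:
        values = matrix.copy()
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("matrix contains non-finite values")
    if (values.to_numpy() < 0).any():
        raise ValueError("matrix contains negative values")
    # lexicographic relabelling makes the result row-order invariant
    values = values.sort_index(axis=0, kind="mergesort").sort_index(axis=1, kind="mergesort")

    row_order, col_order = list(values.index), list(values.columns)
    row_tree = col_tree = None
    if axes in ("rows", "both"):
        if len(values.index) < 2:
            raise ValueError("need at least 2 rows to cluster rows")
        row_order, row_tree, _ = _cluster_axis(values, linkage, metric)
    if axes in ("cols", "both"):
        if len(values.columns) < 2:
            raise ValueError("need at least 2 columns to cluster columns")
        col_order, col_tree, _ = _cluster_axis(values.T, linkage, metric)

    out = values.loc[row_order, col_order]
    if cap is not None:
        if cap <= 0:
            raise ValueError("cap must be positive")
        out = out.clip(upper=cap)
    return ClusterResult(
        matrix_values=out,
        row_order=row_order,
        col_order=col_order,
        row_tree=row_tree,
        col_tree=col_tree,
        linkage_method=linkage,
        distance_metric=metric,
        cap=cap,
    )


def export_heatmap(result: ClusterResult, prefix, render: bool = False) -> list[str]:
    """Write the clustered matrix (TSV) and dendrograms (Newick) to disk.

    Files are ``<prefix>.matrix.tsv``, ``<prefix>.rows.nwk`` and
    ``<prefix>.cols.nwk`` (trees only for the clustered axes); with
    ``render=True`` additionally ``<prefix>.png``.  Repeated exports are
    byte-identical.  Returns the list of paths written.
    """
    prefix = str(prefix)
    written = []
    matrix_path = f"{prefix}.matrix.tsv"
    out = result.matrix_values.copy()
    out.index.name = "row_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.6f", lineterminator="\n")
    written.append(matrix_path)
    for tree, tag in ((result.row_tree, "rows"), (result.col_tree, "cols")):
        if tree is not None:
            path = f"{prefix}.{tag}.nwk"
            with open(path, "w", encoding="utf-8", newline="") as fh:
                fh.write(tree + "\n")
            written.append(path)
    if render:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.4 * len(result.col_order), 2 + 0.25 * len(result.row_order))
        )
        im = ax.imshow(result.matrix_values.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(result.col_order)), result.col_order, rotation=90)
        ax.set_yticks(range(len(result.row_order)), result.row_order, fontsize=6)
        fig.colorbar(im, ax=ax, label="%")
        fig.tight_layout()
        png = f"{prefix}.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)
    return written
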