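"""Combined phylogeny + OTU relative-abundance heatmap figure.

Rows are OTUs ordered by the leaf order of the placement-derived tree,
which is drawn to the left of the heatmap and aligned row-for-row, so that
phylogenetically close OTUs sit next to each other in the abundance
display.  Rendering is deterministic for fixed inputs (fixed SVG hash salt,
no embedded timestamps).
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass

import dendropy
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io_formats import AbundanceMatrix

__all__ = ["HeatmapSpec", "render_heatmap", "normalize_counts"]


def normalize_counts(counts: np.ndarray, mode: str) -> np.ndarray:
    """Displayed heatmap values: per-sample relative abundance or log10 count."""
    counts = np.asarray(counts, dtype=float)
    if mode == "relative":
        totals = counts.sum(axis=0)
        totals[totals == 0] = 1.0
        return counts / totals
    if mode == "log10":
        out = np.zeros_like(counts)
        np.log10(counts, where=counts > 0, out=out)
        return out
    raise ValueError("normalization must be 'relative' or 'log10'")


@dataclass
class HeatmapSpec:
    matrix: AbundanceMatrix
    tree: dendropy.Tree
    output: str
    sample_subset: list[str] | None = None
    normalization: str = "relative"  # or "log10"

    def __post_init__(self) -> None:
        if self.normalization not in ("relative", "log10"):
            raise ValueError("normalization must be 'relative' or 'log10'")


def _tree_coords(tree: dendropy.Tree) -> tuple[list[str], dict, dict]:
    """Leaf order plus (x, y) layout; x = distance from root."""
    order: list[str] = []
    ys: dict[dendropy.Node, float] = {}
    xs: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent_x = xs.get(node.parent_node, 0.0)
        xs[node] = parent_x + (node.edge.length or 0.0) if node.parent_node else 0.0
        if node.is_leaf():
            ys[node] = len(order)
            order.append(node.taxon.label)
    for node in tree.postorder_node_iter():
        if not node.is_leaf():
            ys[node] = float(np.mean([ys[c] for c in node.child_nodes()]))
    return order, xs, ys


def render_heatmap(spec: HeatmapSpec) -> str:
    """Render the figure to ``spec.output`` (SVG or PNG); returns the path."""
    m = spec.matrix
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("cannot render an empty abundance matrix")
    leaf_labels = {leaf.taxon.label for leaf in spec.tree.leaf_node_iter()}
    missing = sorted(set(m.otu_ids) - leaf_labels)
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing}")
    tree = spec.tree
    if leaf_labels - set(m.otu_ids):
        # placement-derived trees carry the queries' closest reference
        # leaves; restrict to the OTU rows being displayed
        from .treesim import induced_subtree

        tree = induced_subtree(tree, sorted(m.otu_ids))

    samples = list(m.sample_ids)
    if spec.sample_subset:
        samples = [
            s for s in samples
            if any(fnmatch.fnmatch(s, pat) for pat in spec.sample_subset)
        ]
        if not samples:
            raise ValueError("sample subset matched no samples")
    col_idx = [m.sample_ids.index(s) for s in samples]

    order, xs, ys = _tree_coords(tree)
    row_idx = [m.otu_ids.index(o) for o in order]
    counts = m.counts[np.ix_(row_idx, col_idx)].astype(float)

    values = normalize_counts(counts, spec.normalization)
    label = "relative abundance" if spec.normalization == "relative" else "log10 count"
    shown = np.ma.masked_where(counts == 0, values)

    n_rows, n_cols = shown.shape
    fig_h = max(2.5, 0.32 * n_rows + 1.2)
    fig_w = max(5.0, 0.45 * n_cols + 4.0)
    fig, (ax_tree, ax_heat) = plt.subplots(
        1, 2, figsize=(fig_w, fig_h), width_ratios=[1, 2], sharey=True
    )

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            ax_tree.plot(
                [xs[node.parent_node], xs[node]], [ys[node], ys[node]],
                color="black", lw=1.0,
            )
        if not node.is_leaf():
            cy = [ys[c] for c in node.child_nodes()]
            ax_tree.plot([xs[node], xs[node]], [min(cy), max(cy)], color="black", lw=1.0)
    ax_tree.set_xlim(left=0)
    ax_tree.invert_yaxis()
    ax_tree.axis("off")

    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.92")  # distinct colour for exact zero
    im = ax_heat.imshow(shown, aspect="auto", cmap=cmap, interpolation="nearest")
    ax_heat.set_xticks(range(n_cols), samples, rotation=90, fontsize=7)
    ax_heat.set_yticks(range(n_rows), order, fontsize=7)
    ax_heat.yaxis.tick_right()
    fig.colorbar(im, ax=ax_heat, label=label, fraction=0.04)
    fig.tight_layout()

    with plt.rc_context({"svg.hashsalt": "ampliplace"}):
        metadata = {"Date": None} if str(spec.output).endswith(".svg") else None
        fig.savefig(spec.output, metadata=metadata)
    plt.close(fig)
    return str(spec.output)
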