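"""Minimal matplotlib tree painting and scatter figures for reports."""

from __future__ import annotations

import numpy as np

from .tree import TimeTree

__all__ = ["tree_layout", "plot_tree"]


def tree_layout(tree: TimeTree) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinates: x = node depth, tips stacked in postorder."""
    x = tree.depths()
    y = np.zeros(tree.n_nodes)
    next_y = 0.0
    for v in tree.postorder:
        v = int(v)
        if v < tree.n_tips:
            y[v] = next_y
            next_y += 1.0
        else:
            ys = [y[c] for c in tree.children[v]]
            y[v] = float(np.mean(ys))
    return x, y


def plot_tree(ax, tree: TimeTree, node_values=None, cmap="coolwarm", vmin=None, vmax=None,
              tip_labels=False, marker_size=18):
    """Rectangular tree plot; ``node_values`` colour the node markers."""
    x, y = tree_layout(tree)
    for v in range(tree.n_nodes):
        p = int(tree.parent[v])
        if p < 0:
            continue
        ax.plot([x[p], x[v]], [y[v], y[v]], color="0.4", lw=0.8)
        ax.plot([x[p], x[p]], [y[p], y[v]], color="0.4", lw=0.8)
    if node_values is not None:
        vals = np.asarray(node_values, dtype=float)
        sc = ax.scatter(x, y, c=vals, cmap=cmap, vmin=vmin, vmax=vmax, s=marker_size,
                        zorder=3, edgecolors="none")
    else:
        sc = None
    if tip_labels:
        for i, lab in enumerate(tree.tip_labels):
            ax.text(x[i] * 1.005, y[i], lab, fontsize=5, va="center")
    ax.set_yticks([])
    ax.set_xlabel("time")
    for side in ("left", "top", "right"):
        ax.spines[side].set_visible(False)
    return sc
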