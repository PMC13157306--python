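"""Static matplotlib views of the network and its centrality profile.

Blue arrows are positive cross-lagged effects, red negative; line width scales
with |beta|.  Requires matplotlib (the ``plot`` extra).
"""

from __future__ import annotations

import numpy as np

from .estimate import DisplayNetwork


def plot_network(display: DisplayNetwork, ax=None):
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    net = display.network
    g = nx.DiGraph()
    for nid, comm in zip(net.node_ids, net.communities):
        g.add_node(nid, community=comm)
    for i, j in zip(*np.nonzero(display.mask)):
        g.add_edge(net.node_ids[i], net.node_ids[j], weight=net.B[i, j])

    pos = nx.circular_layout(g)
    colors = ["#d95f02" if c == "internet" else "#7570b3" for c in
              (g.nodes[n]["community"] for n in g.nodes)]
    nx.draw_networkx_nodes(g, pos, node_color=colors, node_size=700, ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=8, font_color="white", ax=ax)
    weights = [g.edges[e]["weight"] for e in g.edges]
    nx.draw_networkx_edges(
        g, pos, ax=ax, connectionstyle="arc3,rad=0.12",
        width=[8 * abs(w) for w in weights],
        edge_color=["tab:blue" if w > 0 else "tab:red" for w in weights],
    )
    ax.set_axis_off()
    ax.set_title(f"Cross-lagged network (|beta| >= {display.threshold:g})")
    return ax


def plot_centrality(table, ax=None):
    import matplotlib.pyplot as plt

    cols = [c for c in ("out_ei_z", "in_ei_z", "bridge_ei_z") if c in table.columns]
    if not cols:
        cols = ["out_ei", "in_ei", "bridge_ei"]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 7))
    y = np.arange(len(table))[::-1]
    for col, marker in zip(cols, "osd"):
        ax.plot(table[col].to_numpy(), y, marker=marker, label=col.replace("_z", ""))
    ax.set_yticks(y)
    ax.set_yticklabels(table.index)
    ax.legend()
    ax.grid(alpha=0.3)
    ax.set_title("Expected influence")
    return ax
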