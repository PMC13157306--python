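"""Expected-influence centrality for directed cross-lagged networks.

Out-EI sums a node's outgoing signed edges, In-EI its incoming ones; both
exclude the autoregressive diagonal.  Bridge-EI sums the signed edges that
cross between the two pre-specified communities (internet-use purposes vs
depressive symptoms).  All indices are computed on the signed, unfiltered
network — the display threshold is a visualization device only.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .estimate import CLPNetwork

__all__ = ["out_ei", "in_ei", "bridge_ei", "centrality_table", "partition_from_network"]


def _node_index(network: CLPNetwork, node) -> int:
    if isinstance(node, str):
        try:
            return network.node_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
    i = int(node)
    if not 0 <= i < network.p:
        raise KeyError(f"node index {i} out of range")
    return i


def out_ei(network: CLPNetwork, node) -> float:
    """Sum of B[i, j] over j != i: the node's total outgoing influence.

    Accumulated term by term in node order (p is small), so the value is
    bit-identical to a naive loop over the off-diagonal entries.
    """
    i = _node_index(network, node)
    return float(sum(network.B[i, j] for j in range(network.p) if j != i))


def in_ei(network: CLPNetwork, node) -> float:
    """Sum of B[i, j] over i != j: how much the node is predicted by others."""
    j = _node_index(network, node)
    return float(sum(network.B[i, j] for i in range(network.p) if i != j))


def partition_from_network(network: CLPNetwork) -> dict[str, str]:
    return dict(zip(network.node_ids, network.communities))


def bridge_ei(
    network: CLPNetwork, node, partition: Mapping[str, str] | None = None,
    direction: str = "out",
) -> float:
    """Signed influence crossing to the other community (1-step).

    The default, outgoing variant sums B[i, j] over nodes j in the community
    the node does not belong to; ``direction="in"`` sums the incoming
    cross-community edges instead.
    """
    i = _node_index(network, node)
    if partition is None:
        partition = partition_from_network(network)
    missing = [nid for nid in network.node_ids if nid not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    labels = np.array([partition[nid] for nid in network.node_ids])
    if len(set(labels)) != 2:
        raise ValueError("partition must define exactly two communities")
    if direction == "out":
        return float(sum(network.B[i, j] for j in range(network.p)
                         if j != i and labels[j] != labels[i]))
    if direction == "in":
        return float(sum(network.B[j, i] for j in range(network.p)
                         if j != i and labels[j] != labels[i]))
    raise ValueError("direction must be 'out' or 'in'")


def centrality_table(
    network: CLPNetwork,
    partition: Mapping[str, str] | None = None,
    standardized: bool = False,
) -> pd.DataFrame:
    """Out-EI, In-EI and Bridge-EI for every node, canonical order.

    With ``standardized=True`` additional z-scored columns (across nodes) are
    appended, matching the usual centrality-plot convention.
    """
    rows = {
        "node_id": network.node_ids,
        "community": network.communities,
        "out_ei": [out_ei(network, i) for i in range(network.p)],
        "in_ei": [in_ei(network, i) for i in range(network.p)],
        "bridge_ei": [bridge_ei(network, i, partition) for i in range(network.p)],
    }
    df = pd.DataFrame(rows).set_index("node_id")
    if standardized:
        for col in ("out_ei", "in_ei", "bridge_ei"):
            sd = df[col].std(ddof=0)
            df[f"{col}_z"] = (df[col] - df[col].mean()) / sd if sd > 0 else 0.0
    return df
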