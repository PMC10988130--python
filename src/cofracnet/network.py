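"""Differential comparison of two condition-specific interaction networks.

Condition-specific networks (e.g. NF-κB-inhibited vs uninhibited) are compared
edge-wise and node-wise: shared vs condition-unique interactions, the aggregate
(union) network used for downstream validation statistics, and per-protein
interaction counts.  Edge identity is unordered-pair equality; a protein counts
as a network node only while incident to at least one retained edge.
"""

from __future__ import annotations

from dataclasses import dataclass

from .inference import InteractionNetwork

__all__ = [
    "DifferentialNetworkSummary",
    "compare_networks",
    "aggregate_network",
    "degree_table",
    "merge_networks",
]


@dataclass(frozen=True)
class DifferentialNetworkSummary:
    """Edge/node overlap bookkeeping between two networks.

    ``pct_unique`` is the percentage of union edges seen in only one condition:
    ``100 * (n_edges_union - n_edges_shared) / n_edges_union``.
    """

    n_edges_a: int
    n_edges_b: int
    n_edges_shared: int
    n_edges_union: int
    pct_unique: float
    n_nodes_a: int
    n_nodes_b: int
    n_nodes_shared: int
    n_nodes_union: int


def compare_networks(
    a: InteractionNetwork, b: InteractionNetwork
) -> DifferentialNetworkSummary:
    """Shared / unique edge and node counts between two condition networks."""
    shared_edges = a.edges & b.edges
    union_edges = a.edges | b.edges
    shared_nodes = a.nodes & b.nodes
    union_nodes = a.nodes | b.nodes
    n_union = len(union_edges)
    pct_unique = (
        100.0 * (n_union - len(shared_edges)) / n_union if n_union else 0.0
    )
    return DifferentialNetworkSummary(
        n_edges_a=a.n_edges,
        n_edges_b=b.n_edges,
        n_edges_shared=len(shared_edges),
        n_edges_union=n_union,
        pct_unique=pct_unique,
        n_nodes_a=a.n_nodes,
        n_nodes_b=b.n_nodes,
        n_nodes_shared=len(shared_nodes),
        n_nodes_union=len(union_nodes),
    )


def aggregate_network(
    a: InteractionNetwork, b: InteractionNetwork, condition: str = "aggregate"
) -> InteractionNetwork:
    """Union of the two condition networks (node set recomputed from edges)."""
    return InteractionNetwork(condition=condition, edges=a.edges | b.edges)


def merge_networks(
    networks: list[InteractionNetwork], how: str = "union", condition: str = "merged"
) -> InteractionNetwork:
    """Merge replicate-level networks of one condition by union or intersection."""
    if not networks:
        return InteractionNetwork(condition=condition, edges=frozenset())
    edges = set(networks[0].edges)
    for net in networks[1:]:
        if how == "union":
            edges |= net.edges
        elif how == "intersect":
            edges &= net.edges
        else:
            raise ValueError(f"unknown merge mode {how!r}; use 'union' or 'intersect'")
    return InteractionNetwork(condition=condition, edges=frozenset(edges))


def degree_table(n: InteractionNetwork) -> dict[str, int]:
    """Interaction count per network protein (sum of degrees = 2·|edges|)."""
    deg: dict[str, int] = {}
    for a, b in n.edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg
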