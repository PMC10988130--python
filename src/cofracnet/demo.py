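"""Worked-example network constructions.

Builds a pair of condition networks with the edge/node cardinalities observed
in a published NF-κB co-fractionation interactome study of MCF-7 breast cancer
cells (4585 and 4606 interactions with 1623 shared, over 1280 and 1007
proteins with 767 shared), so that the differential-network arithmetic can be
exercised and checked against the reported union of 7568 interactions among
1520 proteins.  The edge sets are deterministic synthetic stand-ins: only
their overlap cardinalities are meaningful, not the identities.
"""

from __future__ import annotations

from .inference import InteractionNetwork

__all__ = ["reported_network_pair", "REPORTED"]

#: The study's reported cardinalities (edges a/b/shared, nodes a/b/shared,
#: and the externally validated interaction count over the union network).
REPORTED = {
    "n_edges_a": 4585,
    "n_edges_b": 4606,
    "n_edges_shared": 1623,
    "n_nodes_a": 1280,
    "n_nodes_b": 1007,
    "n_nodes_shared": 767,
    "n_validated": 2564,
}


def _ring_chords(nodes: list[str], stride: int, count: int) -> list[tuple[str, str]]:
    n = len(nodes)
    return [(nodes[i], nodes[(i + stride) % n]) for i in range(count)]


def reported_network_pair() -> tuple[InteractionNetwork, InteractionNetwork]:
    """Two networks realizing the reported overlap cardinalities exactly.

    Shared edges are ring chords over the 767 shared proteins; each condition's
    unique edges attach its private proteins to the ring and add further
    chords at condition-specific strides, so no edge is double-counted and
    every protein is incident to at least one edge.
    """
    shared_nodes = [f"S{i:04d}" for i in range(REPORTED["n_nodes_shared"])]
    a_only = [f"A{i:04d}" for i in range(REPORTED["n_nodes_a"] - REPORTED["n_nodes_shared"])]
    b_only = [f"B{i:04d}" for i in range(REPORTED["n_nodes_b"] - REPORTED["n_nodes_shared"])]
    ns = len(shared_nodes)

    shared_edges: list[tuple[str, str]] = []
    need, stride = REPORTED["n_edges_shared"], 1
    while need > 0:
        take = min(ns, need)
        shared_edges += _ring_chords(shared_nodes, stride, take)
        need -= take
        stride += 1
    next_stride_a = stride  # condition-unique chords continue at fresh strides

    def unique_edges(private: list[str], total: int, stride0: int):
        edges = [(p, shared_nodes[i % ns]) for i, p in enumerate(private)]
        need, stride = total - len(edges), stride0
        while need > 0:
            take = min(ns, need)
            edges += _ring_chords(shared_nodes, stride, take)
            need -= take
            stride += 1
        return edges, stride

    ua, stride = unique_edges(a_only, REPORTED["n_edges_a"] - REPORTED["n_edges_shared"], next_stride_a)
    ub, _ = unique_edges(b_only, REPORTED["n_edges_b"] - REPORTED["n_edges_shared"], stride)

    net_a = InteractionNetwork.from_edges(shared_edges + ua, condition="inhibited")
    net_b = InteractionNetwork.from_edges(shared_edges + ub, condition="uninhibited")
    return net_a, net_b
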