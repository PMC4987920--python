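"""Decompose a pathway graph into effector-rooted signaling circuits.

A signaling circuit is the subgraph connecting one effector protein back
to every receptor from which it can be reached: the unit whose propagated
activity is computed and compared across conditions.  Membership is
defined by reachability (ancestors of the effector intersected with
descendants of the receptors), which coincides with the union of all
simple receptor-to-effector paths on acyclic graphs and stays
well-defined and polynomial in the presence of feedback loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .pathway_model import PathwayGraph, classify_endpoints

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Circuit:
    """An effector-rooted circuit within one pathway."""

    circuit_id: str
    pathway_id: str
    effector: str
    member_nodes: frozenset[str]
    member_edges: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if self.effector not in self.member_nodes:
            raise ValueError(
                f"circuit {self.circuit_id!r}: effector not among member nodes"
            )


def extract_circuits(graph: PathwayGraph) -> list[Circuit]:
    """Build one circuit per effector node, sorted by circuit id.

    Member nodes are those lying on some directed receptor-to-effector
    route: nodes from which the effector is reachable, intersected with
    nodes reachable from at least one receptor.  Member edges are the
    pathway edges induced on the member set.  An effector unreachable
    from every receptor yields a degenerate single-node circuit with a
    warning.
    """
    receptors, effectors = classify_endpoints(graph)
    g = graph.to_networkx()
    reachable_from_receptors: set[str] = set()
    for r in receptors:
        reachable_from_receptors.add(r)
        reachable_from_receptors |= nx.descendants(g, r)

    circuits = []
    for effector in sorted(effectors):
        upstream = {effector} | nx.ancestors(g, effector)
        members = upstream & reachable_from_receptors
        if effector not in members:
            logger.warning(
                "pathway %s: effector %s is unreachable from every receptor",
                graph.pathway_id,
                effector,
            )
            members = {effector}
        member_edges = frozenset(
            e.key
            for e in graph.edges
            if e.source in members and e.target in members
        )
        circuits.append(
            Circuit(
                circuit_id=f"{graph.pathway_id}:{effector}",
                pathway_id=graph.pathway_id,
                effector=effector,
                member_nodes=frozenset(members),
                member_edges=member_edges,
            )
        )
    return circuits


def circuits_containing(
    gene: str, circuits: list[Circuit], graph: PathwayGraph
) -> list[str]:
    """Ids of all circuits with a member node whose gene ids include ``gene``.

    A gene can sit on several circuits at once (shared upstream segments,
    multiple pathways); an unknown gene simply yields an empty list.
    """
    hits = []
    for circuit in circuits:
        for node_id in circuit.member_nodes:
            node = graph.nodes.get(node_id)
            if node is not None and gene in node.gene_ids:
                hits.append(circuit.circuit_id)
                break
    return hits
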