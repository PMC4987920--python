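"""Signed pathway graphs: data model, readers, and endpoint classification.

A pathway is a directed graph whose nodes stand for gene products (or
complexes/families of them) and whose edges carry a sign: ``activation``
or ``inhibition``.  Receptor nodes (no incoming edge) are where stimulus
enters the network; effector nodes (no outgoing edge) trigger the cell's
functional response.

Two readers are provided: a plain tab-separated edge-list dialect, which
is the canonical interchange format of this package, and a read-only
KGML (KEGG pathway XML) importer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"
NODE_CLASSES = ("simple", "complex", "family")
ROLES = ("receptor", "effector")


class PathwayError(ValueError):
    """Raised on malformed pathway input or an unusable topology."""


@dataclass(frozen=True)
class Edge:
    """A signed directed interaction between two pathway nodes."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise PathwayError(f"unknown edge sign {self.sign!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.sign)


@dataclass(frozen=True)
class Node:
    """A pathway node: one gene, or a complex/family of several genes.

    ``node_class`` controls how member gene activities are pooled into a
    single node activity: ``complex`` takes the minimum (all subunits
    required), ``family``/multi-gene ``simple`` takes the mean.  ``role``
    optionally pins the node as receptor or effector regardless of its
    degree, which is needed for graphs where every node lies on a cycle.
    """

    node_id: str
    gene_ids: tuple[str, ...]
    node_class: str = "simple"
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise PathwayError(f"node {self.node_id!r} has no gene ids")
        if self.node_class not in NODE_CLASSES:
            raise PathwayError(
                f"node {self.node_id!r}: unknown node class {self.node_class!r}"
            )
        if self.role is not None and self.role not in ROLES:
            raise PathwayError(f"node {self.node_id!r}: unknown role {self.role!r}")


class PathwayGraph:
    """A validated signed directed pathway graph.

    Self-loop edges are dropped (with a warning) and duplicate edges are
    de-duplicated at construction time; edge endpoints must be declared
    nodes.
    """

    def __init__(
        self,
        pathway_id: str,
        name: str,
        nodes: Iterable[Node],
        edges: Iterable[Edge],
    ) -> None:
        self.pathway_id = pathway_id
        self.name = name
        self.nodes: dict[str, Node] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise PathwayError(
                    f"pathway {pathway_id!r}: duplicate node id {node.node_id!r}"
                )
            self.nodes[node.node_id] = node
        self.edges: list[Edge] = []
        seen: set[tuple[str, str, str]] = set()
        for edge in edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.nodes:
                    raise PathwayError(
                        f"pathway {pathway_id!r}: edge endpoint {endpoint!r} "
                        "is not a declared node"
                    )
            if edge.source == edge.target:
                logger.warning(
                    "pathway %s: dropping self-loop on node %s",
                    pathway_id,
                    edge.source,
                )
                continue
            if edge.key in seen:
                logger.warning(
                    "pathway %s: duplicate edge %s -> %s (%s) de-duplicated",
                    pathway_id,
                    edge.source,
                    edge.target,
                    edge.sign,
                )
                continue
            seen.add(edge.key)
            self.edges.append(edge)

    def to_networkx(self) -> nx.DiGraph:
        """Export as a networkx DiGraph with a ``sign`` edge attribute."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def gene_set(self) -> set[str]:
        """All gene identifiers mentioned by any node."""
        return {g for node in self.nodes.values() for g in node.gene_ids}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return (
            self.pathway_id == other.pathway_id
            and self.nodes == other.nodes
            and set(e.key for e in self.edges) == set(e.key for e in other.edges)
        )

    def __repr__(self) -> str:
        return (
            f"PathwayGraph({self.pathway_id!r}, nodes={len(self.nodes)}, "
            f"edges={len(self.edges)})"
        )


def _parse_sign(token: str, path: Path, lineno: int) -> str:
    sign = token.strip().lower()
    if sign not in (ACTIVATION, INHIBITION):
        raise PathwayError(
            f"{path}:{lineno}: unknown sign token {token!r} "
            f"(expected 'activation' or 'inhibition')"
        )
    return sign


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def load_edge_list(
    edge_file: str | Path,
    node_file: str | Path | None = None,
    pathway_id: str | None = None,
    name: str | None = None,
) -> PathwayGraph:
    """Load a pathway from the edge-list TSV dialect.

    The edge file has columns ``source  target  sign`` (header optional,
    ``#`` comments ignored); signs are case-insensitive.  The optional
    node file has columns ``node_id  gene_ids  node_class  [role]`` with
    gene ids comma-separated.  Nodes absent from the node file become
    simple nodes whose single gene id equals the node id.
    """
    edge_path = Path(edge_file)
    if pathway_id is None:
        pathway_id = edge_path.stem
    edges: list[Edge] = []
    endpoints: list[str] = []
    for lineno, fields in _data_lines(edge_path):
        if [f.lower() for f in fields[:3]] == ["source", "target", "sign"]:
            continue
        if len(fields) < 3:
            raise PathwayError(
                f"{edge_path}:{lineno}: expected 3 columns "
                f"(source, target, sign), got {len(fields)}"
            )
        source, target = fields[0].strip(), fields[1].strip()
        sign = _parse_sign(fields[2], edge_path, lineno)
        edges.append(Edge(source, target, sign))
        endpoints.extend((source, target))

    declared: dict[str, Node] = {}
    if node_file is not None:
        node_path = Path(node_file)
        for lineno, fields in _data_lines(node_path):
            if [f.lower() for f in fields[:2]] == ["node_id", "gene_ids"]:
                continue
            if len(fields) < 2:
                raise PathwayError(
                    f"{node_path}:{lineno}: expected at least 2 columns "
                    f"(node_id, gene_ids), got {len(fields)}"
                )
            node_id = fields[0].strip()
            gene_ids = tuple(
                g.strip() for g in fields[1].split(",") if g.strip()
            )
            node_class = fields[2].strip().lower() if len(fields) > 2 else "simple"
            role = fields[3].strip().lower() if len(fields) > 3 else None
            if not node_class:
                node_class = "simple"
            try:
                declared[node_id] = Node(node_id, gene_ids, node_class, role or None)
            except PathwayError as exc:
                raise PathwayError(f"{node_path}:{lineno}: {exc}") from exc

    nodes: dict[str, Node] = dict(declared)
    for node_id in endpoints:
        if node_id not in nodes:
            nodes[node_id] = Node(node_id, (node_id,))
    return PathwayGraph(pathway_id, name or pathway_id, nodes.values(), edges)


def write_edge_list(
    graph: PathwayGraph,
    edge_file: str | Path,
    node_file: str | Path | None = None,
) -> None:
    """Write a pathway back to the edge-list dialect (round-trip safe)."""
    with open(edge_file, "w") as fh:
        fh.write("source\ttarget\tsign\n")
        for e in sorted(graph.edges, key=lambda e: e.key):
            fh.write(f"{e.source}\t{e.target}\t{e.sign}\n")
    if node_file is not None:
        with open(node_file, "w") as fh:
            fh.write("node_id\tgene_ids\tnode_class\trole\n")
            for node in sorted(graph.nodes.values(), key=lambda n: n.node_id):
                fh.write(
                    f"{node.node_id}\t{','.join(node.gene_ids)}"
                    f"\t{node.node_class}\t{node.role or ''}\n"
                )


# KGML relation subtypes mapped onto edge signs; everything else is skipped.
_KGML_SIGN = {
    "activation": ACTIVATION,
    "expression": ACTIVATION,
    "inhibition": INHIBITION,
    "repression": INHIBITION,
}


def load_kgml(kgml_file: str | Path) -> PathwayGraph:
    """Load a pathway from a KGML (KEGG pathway XML) file.

    Only ``entry`` elements of type ``gene`` become nodes; all gene ids
    listed in the entry ``name`` attribute are retained (multi-gene
    entries become ``family`` nodes).  Relation subtypes activation /
    expression map to activation edges and inhibition / repression to
    inhibition edges; other subtypes and entry types (compound, map,
    group, ...) are skipped with a logged count.
    """
    path = Path(kgml_file)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise PathwayError(f"{path}: invalid KGML XML: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name", path.stem).replace("path:", "")
    title = root.get("title", pathway_id)

    nodes: dict[str, Node] = {}
    skipped_entries = 0
    for entry in root.iter("entry"):
        if entry.get("type") != "gene":
            skipped_entries += 1
            continue
        entry_id = entry.get("id")
        gene_ids = tuple(entry.get("name", "").split())
        if not entry_id or not gene_ids:
            skipped_entries += 1
            continue
        node_class = "simple" if len(gene_ids) == 1 else "family"
        nodes[entry_id] = Node(entry_id, gene_ids, node_class)

    edges: list[Edge] = []
    skipped_relations = 0
    for relation in root.iter("relation"):
        src, tgt = relation.get("entry1"), relation.get("entry2")
        if src not in nodes or tgt not in nodes:
            skipped_relations += 1
            continue
        sign = None
        for subtype in relation.iter("subtype"):
            sign = _KGML_SIGN.get(subtype.get("name", "").lower())
            if sign is not None:
                break
        if sign is None:
            skipped_relations += 1
            continue
        edges.append(Edge(src, tgt, sign))

    if skipped_entries or skipped_relations:
        logger.info(
            "%s: skipped %d non-gene entries and %d unusable relations",
            path,
            skipped_entries,
            skipped_relations,
        )
    if not edges:
        logger.warning("%s: KGML contained no usable signed relations", path)
    return PathwayGraph(pathway_id, title, nodes.values(), edges)


def classify_endpoints(graph: PathwayGraph) -> tuple[set[str], set[str]]:
    """Split pathway nodes into receptors and effectors.

    Receptors are nodes with in-degree 0, effectors nodes with out-degree
    0 (an isolated node is both).  Explicit ``role`` annotations on nodes
    are added on top of the topological classification, which is the only
    way to obtain receptors in a graph where every node lies on a cycle.
    """
    g = graph.to_networkx()
    receptors = {n for n in g if g.in_degree(n) == 0}
    effectors = {n for n in g if g.out_degree(n) == 0}
    receptors |= {n.node_id for n in graph.nodes.values() if n.role == "receptor"}
    effectors |= {n.node_id for n in graph.nodes.values() if n.role == "effector"}
    if graph.nodes and not receptors:
        raise PathwayError(
            f"pathway {graph.pathway_id!r}: every node lies on a cycle, so no "
            "receptor can be inferred from the topology; annotate receptors "
            "explicitly via the node file 'role' column"
        )
    return receptors, effectors
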