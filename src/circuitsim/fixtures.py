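"""Deterministic synthetic pathways, profiles and drug tables for testing.

Everything here is seeded: a single integer seed fully determines the
output and no global random state is touched.  The generated topologies
are random layered DAGs (optionally with added back-edges to create
feedback loops); they exercise the propagation machinery but make no
attempt to mimic the degree statistics of curated pathway databases.

The module also hosts the brute-force propagation oracle used by the
test suite: a naive synchronous iteration of the signal update rule,
written against a dense matrix formulation so it shares no code with the
production solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .expression_io import ExpressionProfile
from .pathway_model import (
    ACTIVATION,
    INHIBITION,
    Edge,
    Node,
    PathwayGraph,
    write_edge_list,
)
from .propagation_engine import PropagationConfig, SignalState, node_activity


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic pathway."""

    seed: int
    n_nodes: int = 8
    edge_density: float = 0.4
    inhibition_fraction: float = 0.25
    cyclic: bool = False

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise ValueError("inhibition_fraction must lie in [0, 1]")


_MAX_ATTEMPTS = 50


def generate_pathway(spec: FixtureSpec, pathway_id: str | None = None) -> PathwayGraph:
    """Generate a random weakly connected signed DAG (plus back-edges if cyclic).

    Nodes are ordered and forward edges drawn independently with
    probability ``edge_density``; each edge is an inhibition with
    probability ``inhibition_fraction``.  Topological ordering guarantees
    at least one receptor and one effector.  With ``cyclic=True`` a
    back-edge closing a directed cycle is added on top, choosing a target
    that already has another incoming edge so at least one receptor
    survives.  Draws are retried until the graph is weakly connected
    (error after a bounded number of attempts).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    if pathway_id is None:
        pathway_id = f"synth{spec.seed}"
    for _ in range(_MAX_ATTEMPTS):
        edges: list[tuple[int, int]] = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < spec.edge_density:
                    edges.append((i, j))
        if not edges:
            continue
        # weak connectivity check via union-find over undirected edges
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in edges:
            parent[find(i)] = find(j)
        if len({find(i) for i in range(n)}) != 1:
            continue

        signs = [
            INHIBITION if rng.random() < spec.inhibition_fraction else ACTIVATION
            for _ in edges
        ]
        if spec.cyclic:
            # close a cycle i -> j -> ... plus j' -> i where target i has
            # other incoming edges, so in-degree-0 receptors survive
            indeg = {k: 0 for k in range(n)}
            for _, j in edges:
                indeg[j] += 1
            candidates = [
                (i, j) for (i, j) in edges if indeg[i] >= 1
            ]
            if not candidates:
                continue
            i, j = candidates[rng.integers(len(candidates))]
            edges.append((j, i))
            signs.append(
                INHIBITION
                if rng.random() < spec.inhibition_fraction
                else ACTIVATION
            )
        nodes = [Node(f"N{k}", (f"G{k}",)) for k in range(n)]
        edge_objs = [
            Edge(f"N{i}", f"N{j}", sign)
            for (i, j), sign in zip(edges, signs)
        ]
        return PathwayGraph(pathway_id, pathway_id, nodes, edge_objs)
    raise ValueError(
        f"could not generate a connected pathway for {spec!r} in "
        f"{_MAX_ATTEMPTS} attempts; increase edge_density"
    )


def generate_profile(graph: PathwayGraph, seed: int) -> ExpressionProfile:
    """Uniform [0, 1] activity for every gene in the graph, seeded."""
    rng = np.random.default_rng(seed)
    genes = sorted(graph.gene_set())
    return ExpressionProfile(
        sample_id=f"synthetic-{seed}",
        values={g: float(rng.random()) for g in genes},
    )


def oracle_propagate(
    graph: PathwayGraph,
    profile: ExpressionProfile,
    config: PropagationConfig | None = None,
    steps: int = 100_000,
    receptors: set[str] | None = None,
) -> SignalState:
    """Ground-truth propagation by naive synchronous iteration.

    Runs the dense-matrix form of the update rule for ``steps``
    synchronous iterations starting from S = v, with no convergence
    test.  Iteration is deterministic, so once two consecutive states are
    bitwise identical every later state is too and the loop can stop
    with the exact same result it would reach after all ``steps``.
    Intended for graphs of a few dozen nodes at most.
    """
    config = config or PropagationConfig()
    receptors = receptors or set()
    order = sorted(graph.nodes)
    idx = {n: k for k, n in enumerate(order)}
    n = len(order)
    v = np.array(
        [
            node_activity(graph.nodes[node_id], profile, config)
            for node_id in order
        ]
    )
    act = np.zeros((n, n))
    inh = np.zeros((n, n))
    for e in graph.edges:
        if e.target in receptors:
            continue
        mat = act if e.sign == ACTIVATION else inh
        mat[idx[e.target], idx[e.source]] = 1.0
    has_act = act.sum(axis=1) > 0
    receptor_mask = np.array([node_id in receptors for node_id in order])

    if steps < 1:
        raise ValueError("steps must be >= 1")
    s = v.copy()
    iterations = 0
    residual = 0.0
    for step in range(steps):
        # log-domain products over parents; floor avoids log(0) = -inf
        log1m = np.log(np.maximum(1.0 - s, 1e-300))
        act_factor = np.where(has_act, 1.0 - np.exp(act @ log1m), 1.0)
        inh_factor = np.exp(inh @ log1m)
        s_new = v * act_factor * inh_factor
        s_new[receptor_mask] = v[receptor_mask]
        iterations = step + 1
        residual = float(np.max(np.abs(s_new - s)))
        if residual == 0.0:
            break
        s = s_new
    signals = {node_id: float(s_new[idx[node_id]]) for node_id in order}
    return SignalState(
        signals,
        iterations=iterations,
        converged=residual <= config.tolerance,
        residual=residual,
    )


def generate_drug_table(
    graph: PathwayGraph, seed: int, n_drugs: int = 2, targets_per_drug: int = 2
) -> dict[str, list[tuple[str, float]]]:
    """Random drug -> [(target gene, weight 0)] table over the graph's genes."""
    rng = np.random.default_rng(seed)
    genes = sorted(graph.gene_set())
    table: dict[str, list[tuple[str, float]]] = {}
    for d in range(n_drugs):
        k = min(targets_per_drug, len(genes))
        chosen = rng.choice(len(genes), size=k, replace=False)
        table[f"drug{d + 1}"] = [(genes[int(i)], 0.0) for i in sorted(chosen)]
    return table


def write_bundle(
    out_dir: str | Path,
    seed: int,
    n_pathways: int = 2,
    n_nodes: int = 8,
    edge_density: float = 0.4,
    inhibition_fraction: float = 0.25,
    cyclic: bool = False,
) -> dict[str, Path]:
    """Write a ready-to-run fixture bundle (pathways, profile, drug table).

    Returns a map of logical names to the files written: pathway edge
    lists under ``pathways/``, a single-sample expression TSV and a
    drug-target TSV.
    """
    out = Path(out_dir)
    pathway_dir = out / "pathways"
    pathway_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    graphs = []
    for p in range(n_pathways):
        spec = FixtureSpec(
            seed=seed + p,
            n_nodes=n_nodes,
            edge_density=edge_density,
            inhibition_fraction=inhibition_fraction,
            cyclic=cyclic,
        )
        graph = generate_pathway(spec, pathway_id=f"pw{p + 1}")
        graphs.append(graph)
        edge_path = pathway_dir / f"{graph.pathway_id}.tsv"
        write_edge_list(graph, edge_path)
        paths[graph.pathway_id] = edge_path

    genes = sorted(set().union(*(g.gene_set() for g in graphs)))
    rng = np.random.default_rng(seed)
    profile_path = out / "expression.tsv"
    with open(profile_path, "w") as fh:
        fh.write("gene\tS1\n")
        for gene in genes:
            fh.write(f"{gene}\t{rng.random():.6f}\n")
    paths["expression"] = profile_path

    drug_path = out / "drug_table.tsv"
    table = generate_drug_table(graphs[0], seed)
    with open(drug_path, "w") as fh:
        fh.write("drug\ttarget_gene\tdefault_weight\n")
        for drug in sorted(table):
            for gene, weight in table[drug]:
                fh.write(f"{drug}\t{gene}\t{weight:g}\n")
    paths["drug_table"] = drug_path
    return paths
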