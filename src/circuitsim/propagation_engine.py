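"""Receptor-to-effector signal propagation with activation/inhibition edges.

Gene activity values in [0, 1] are read as probabilities that the gene
product is functional.  Signal intensity at a node combines three
independent requirements: the node's own product must be active, at
least one activating input must carry signal, and no inhibiting input
may carry signal.  Writing S_n for the signal at node n and v_n for its
activity, the update rule is

    S_n = v_n * (1 - prod_a (1 - S_a)) * prod_i (1 - S_i)

with a running over activating parents and i over inhibiting parents;
the activation factor defaults to 1 when a node has no activating
parent, so source nodes (receptors) carry S_n = v_n, i.e. stimulus is
assumed present at full strength and the expression profile is the sole
driver of the signal.

Acyclic graphs are solved exactly in one topological sweep.  Graphs with
feedback loops are solved by synchronous (Jacobi) fixed-point iteration
from S = v; non-convergence is reported on the result, not raised.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import networkx as nx

from .circuit_extraction import Circuit
from .expression_io import ExpressionProfile
from .pathway_model import ACTIVATION, Node, PathwayGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationConfig:
    """Numerical knobs for the propagation solver.

    ``missing_gene_activity`` is the neutral activity assigned to pathway
    genes absent from the expression profile: 0.5 neither kills nor
    saturates the signal passing through such nodes.
    """

    tolerance: float = 1e-6
    max_iterations: int = 1000
    missing_gene_activity: float = 0.5

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.missing_gene_activity <= 1.0:
            raise ValueError("missing_gene_activity must lie in [0, 1]")


@dataclass
class SignalState:
    """Propagation result: per-node signal intensities plus convergence info."""

    signals: dict[str, float]
    iterations: int
    converged: bool
    residual: float


def node_activity(
    node: Node, profile: ExpressionProfile, config: PropagationConfig
) -> float:
    """Pool a node's member gene activities into one value in [0, 1].

    Complexes take the minimum over members (every subunit required);
    families and multi-gene simple nodes take the mean.  Genes missing
    from the profile contribute ``config.missing_gene_activity``.
    """
    activities = []
    missing = []
    for gene in node.gene_ids:
        value = profile.values.get(gene)
        if value is None:
            missing.append(gene)
            value = config.missing_gene_activity
        activities.append(value)
    if missing:
        logger.debug(
            "node %s: genes %s missing from profile, using default %.3g",
            node.node_id,
            ",".join(missing),
            config.missing_gene_activity,
        )
    if node.node_class == "complex":
        return min(activities)
    return statistics.fmean(activities)


def _update(
    node_id: str,
    v: dict[str, float],
    signals: dict[str, float],
    act_parents: dict[str, list[str]],
    inh_parents: dict[str, list[str]],
) -> float:
    act = act_parents[node_id]
    inh = inh_parents[node_id]
    if act:
        miss = 1.0
        for a in act:
            miss *= 1.0 - signals[a]
        act_factor = 1.0 - miss
    else:
        act_factor = 1.0
    inh_factor = 1.0
    for i in inh:
        inh_factor *= 1.0 - signals[i]
    return v[node_id] * act_factor * inh_factor


def propagate(
    graph: PathwayGraph,
    profile: ExpressionProfile,
    config: PropagationConfig | None = None,
    receptors: set[str] | None = None,
) -> SignalState:
    """Propagate gene activity from receptors to effectors.

    ``receptors`` optionally pins nodes whose signal is held at their own
    activity regardless of incoming edges (needed when receptor status
    comes from explicit annotation rather than in-degree 0).  On a DAG
    the result is exact after a single topological sweep; otherwise
    synchronous fixed-point iteration runs until the maximum absolute
    change drops below ``tolerance`` or ``max_iterations`` is hit, in
    which case the state is returned with ``converged=False``.
    """
    config = config or PropagationConfig()
    receptors = receptors or set()
    g = graph.to_networkx()
    v = {
        n.node_id: node_activity(n, profile, config)
        for n in graph.nodes.values()
    }
    act_parents: dict[str, list[str]] = {n: [] for n in graph.nodes}
    inh_parents: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for e in graph.edges:
        if e.target in receptors:
            continue
        (act_parents if e.sign == ACTIVATION else inh_parents)[e.target].append(
            e.source
        )

    if nx.is_directed_acyclic_graph(g):
        signals: dict[str, float] = {}
        for node_id in nx.topological_sort(g):
            if node_id in receptors:
                signals[node_id] = v[node_id]
            else:
                signals[node_id] = _update(
                    node_id, v, signals, act_parents, inh_parents
                )
        return SignalState(signals, iterations=1, converged=True, residual=0.0)

    signals = dict(v)
    residual = float("inf")
    for iteration in range(1, config.max_iterations + 1):
        new_signals = {}
        for node_id in graph.nodes:
            if node_id in receptors:
                new_signals[node_id] = v[node_id]
            else:
                new_signals[node_id] = _update(
                    node_id, v, signals, act_parents, inh_parents
                )
        residual = max(
            abs(new_signals[n] - signals[n]) for n in graph.nodes
        )
        signals = new_signals
        if residual <= config.tolerance:
            return SignalState(signals, iteration, True, residual)
    logger.warning(
        "pathway %s: fixed-point iteration did not converge in %d iterations "
        "(residual %.3g)",
        graph.pathway_id,
        config.max_iterations,
        residual,
    )
    return SignalState(signals, config.max_iterations, False, residual)


def circuit_subgraph(circuit: Circuit, graph: PathwayGraph) -> PathwayGraph:
    """The pathway restricted to a circuit's member nodes and edges."""
    nodes = [graph.nodes[n] for n in sorted(circuit.member_nodes)]
    edge_keys = set(circuit.member_edges)
    edges = [e for e in graph.edges if e.key in edge_keys]
    return PathwayGraph(circuit.circuit_id, circuit.circuit_id, nodes, edges)


def propagate_circuit(
    circuit: Circuit,
    graph: PathwayGraph,
    profile: ExpressionProfile,
    config: PropagationConfig | None = None,
) -> SignalState:
    """Propagate on the circuit subgraph only.

    Restricting propagation to the circuit's own nodes and edges keeps
    interventions outside the circuit from leaking in except through
    member nodes.
    """
    sub = circuit_subgraph(circuit, graph)
    annotated = {
        n.node_id for n in sub.nodes.values() if n.role == "receptor"
    }
    return propagate(sub, profile, config, receptors=annotated or None)


def circuit_activity(circuit: Circuit, state: SignalState) -> float:
    """The circuit's activity: its effector node's signal intensity."""
    if circuit.effector not in state.signals:
        raise KeyError(
            f"circuit {circuit.circuit_id!r}: effector {circuit.effector!r} "
            "missing from the signal state"
        )
    return state.signals[circuit.effector]


def circuit_activities(
    graph: PathwayGraph,
    circuits: list[Circuit],
    profile: ExpressionProfile,
    config: PropagationConfig | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Activities for every circuit of one pathway.

    Returns (circuit_id -> activity, ids of circuits whose fixed-point
    iteration failed to converge).
    """
    activities: dict[str, float] = {}
    not_converged: list[str] = []
    for circuit in circuits:
        state = propagate_circuit(circuit, graph, profile, config)
        if not state.converged:
            not_converged.append(circuit.circuit_id)
        activities[circuit.circuit_id] = circuit_activity(circuit, state)
    return activities, not_converged
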