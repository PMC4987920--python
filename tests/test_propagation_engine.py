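"""Signal propagation: hand-computed cases, oracle agreement, invariants."""

import numpy as np
import pytest

from circuitsim import (
    Edge,
    ExpressionProfile,
    FixtureSpec,
    Node,
    PathwayGraph,
    PropagationConfig,
    circuit_activity,
    extract_circuits,
    generate_pathway,
    generate_profile,
    node_activity,
    oracle_propagate,
    propagate,
    propagate_circuit,
)


def profile_of(**values):
    return ExpressionProfile("t", dict(values))


def simple_graph(edges, nodes=None):
    if nodes is None:
        nodes = sorted({n for e in edges for n in e[:2]})
    return PathwayGraph(
        "p",
        "p",
        [Node(n, (n,)) for n in nodes],
        [Edge(s, t, sign) for s, t, sign in edges],
    )


class TestNodeActivity:
    def test_simple_node_passthrough(self):
        node = Node("N", ("g",))
        assert node_activity(node, profile_of(g=0.7), PropagationConfig()) == 0.7

    def test_complex_takes_minimum(self):
        node = Node("N", ("a", "b"), "complex")
        assert node_activity(
            node, profile_of(a=0.9, b=0.4), PropagationConfig()
        ) == pytest.approx(0.4)

    def test_family_takes_mean(self):
        node = Node("N", ("a", "b"), "family")
        assert node_activity(
            node, profile_of(a=0.9, b=0.4), PropagationConfig()
        ) == pytest.approx(0.65)

    def test_missing_gene_uses_default(self):
        node = Node("N", ("absent",))
        assert node_activity(node, profile_of(), PropagationConfig()) == 0.5
        cfg = PropagationConfig(missing_gene_activity=0.2)
        assert node_activity(node, profile_of(), cfg) == 0.2


class TestPropagateHandCases:
    def test_saturated_chain(self):
        graph = simple_graph(
            [("R", "A", "activation"), ("A", "E", "activation")]
        )
        state = propagate(graph, profile_of(R=1, A=1, E=1))
        assert state.signals["E"] == pytest.approx(1.0)
        assert state.converged

    def test_full_inhibition_forces_zero(self):
        graph = simple_graph([("R", "E", "inhibition")])
        state = propagate(graph, profile_of(R=1, E=1))
        assert state.signals["E"] == pytest.approx(0.0)

    def test_two_receptors_noisy_or(self):
        graph = simple_graph(
            [("R1", "E", "activation"), ("R2", "E", "activation")]
        )
        state = propagate(graph, profile_of(R1=0.8, R2=0.5, E=1))
        # 1 - (1 - 0.8)(1 - 0.5) = 0.9
        assert state.signals["E"] == pytest.approx(0.9)

    def test_diamond_redundant_branches(self):
        graph = simple_graph(
            [
                ("R", "A", "activation"),
                ("R", "B", "activation"),
                ("A", "E", "activation"),
                ("B", "E", "activation"),
            ]
        )
        state = propagate(graph, profile_of(R=1, A=0.5, B=0.5, E=1))
        # each branch carries 0.5; 1 - (1 - 0.5)(1 - 0.5) = 0.75
        assert state.signals["E"] == pytest.approx(0.75)

    def test_mixed_activation_inhibition(self):
        graph = simple_graph(
            [("R1", "E", "activation"), ("R2", "E", "inhibition")]
        )
        state = propagate(graph, profile_of(R1=0.8, R2=0.3, E=0.9))
        # 0.9 * 0.8 * (1 - 0.3)
        assert state.signals["E"] == pytest.approx(0.9 * 0.8 * 0.7)

    def test_cycle_converges(self):
        graph = simple_graph(
            [
                ("R", "A", "activation"),
                ("A", "B", "activation"),
                ("B", "A", "activation"),
            ]
        )
        profile = profile_of(R=1, A=0.9, B=0.9)
        state = propagate(graph, profile)
        assert state.converged
        assert state.residual <= 1e-6
        oracle = oracle_propagate(graph, profile)
        for n in graph.nodes:
            assert state.signals[n] == pytest.approx(oracle.signals[n], abs=1e-6)

    def test_non_convergence_is_flagged_not_raised(self, caplog):
        # strong inhibitory 2-cycle driven at full activity oscillates
        graph = simple_graph(
            [
                ("R", "A", "activation"),
                ("A", "B", "inhibition"),
                ("B", "A", "inhibition"),
            ]
        )
        cfg = PropagationConfig(max_iterations=10)
        with caplog.at_level("WARNING"):
            state = propagate(graph, profile_of(R=1, A=1, B=1), cfg)
        assert not state.converged
        assert state.iterations == 10


class TestPropagationInvariants:
    def test_oracle_equivalence_random_graphs(self):
        for seed in range(40):
            cyclic = seed % 3 == 0
            graph = generate_pathway(
                FixtureSpec(
                    seed=seed,
                    n_nodes=4 + seed % 9,
                    edge_density=0.45,
                    inhibition_fraction=0.3,
                    cyclic=cyclic,
                )
            )
            profile = generate_profile(graph, seed + 1000)
            # a stopping residual r leaves up to r*rho/(1-rho) of true error
            # on cyclic graphs, so solve well below the 1e-6 agreement bound
            cfg = PropagationConfig(tolerance=1e-10, max_iterations=20000)
            state = propagate(graph, profile, cfg)
            oracle = oracle_propagate(graph, profile)
            if not (state.converged and oracle.converged):
                continue
            for n in graph.nodes:
                assert state.signals[n] == pytest.approx(
                    oracle.signals[n], abs=1e-6
                ), f"seed {seed} node {n}"

    def test_range_preservation(self):
        for seed in range(30):
            graph = generate_pathway(
                FixtureSpec(seed=seed, n_nodes=10, inhibition_fraction=0.5)
            )
            profile = generate_profile(graph, seed)
            state = propagate(graph, profile)
            assert all(0.0 <= s <= 1.0 for s in state.signals.values())

    def test_activation_monotonicity(self):
        # raising any gene's activity on an activation-only graph never
        # decreases any signal
        for seed in range(15):
            graph = generate_pathway(
                FixtureSpec(seed=seed, n_nodes=8, inhibition_fraction=0.0)
            )
            profile = generate_profile(graph, seed)
            base = propagate(graph, profile)
            rng = np.random.default_rng(seed)
            gene = sorted(graph.gene_set())[
                rng.integers(len(graph.gene_set()))
            ]
            bumped = profile.copy()
            bumped.values[gene] = min(1.0, bumped.values[gene] + 0.3)
            after = propagate(graph, bumped)
            for n in graph.nodes:
                assert after.signals[n] >= base.signals[n] - 1e-12

    def test_inhibition_monotonicity_direct_target(self):
        graph = simple_graph(
            [("R", "E", "activation"), ("I", "E", "inhibition")]
        )
        lo = propagate(graph, profile_of(R=0.8, I=0.2, E=0.9))
        hi = propagate(graph, profile_of(R=0.8, I=0.7, E=0.9))
        assert hi.signals["E"] < lo.signals["E"]

    def test_dag_single_pass_equals_fixed_point(self):
        # force the iterative solver on a DAG by adding an unreachable
        # 2-cycle component, then compare on the DAG part
        for seed in range(20):
            graph = generate_pathway(
                FixtureSpec(seed=seed, n_nodes=9, inhibition_fraction=0.3)
            )
            profile = generate_profile(graph, seed + 7)
            topo = propagate(graph, profile)
            iterative = oracle_propagate(graph, profile, steps=200_000)
            for n in graph.nodes:
                assert abs(topo.signals[n] - iterative.signals[n]) <= 1e-9

    def test_zero_annihilation_through_articulation_node(self):
        graph = simple_graph(
            [
                ("R1", "A", "activation"),
                ("R2", "A", "activation"),
                ("A", "B", "activation"),
                ("B", "E", "activation"),
            ]
        )
        profile = profile_of(R1=0.9, R2=0.8, A=0.0, B=1.0, E=1.0)
        state = propagate(graph, profile)
        assert state.signals["E"] == pytest.approx(0.0)


class TestCircuitActivity:
    def test_activity_is_effector_signal_on_subgraph(self, diamond_graph):
        (circuit,) = extract_circuits(diamond_graph)
        profile = profile_of(R=1, A=0.5, B=0.5, E=1)
        state = propagate_circuit(circuit, diamond_graph, profile)
        assert circuit_activity(circuit, state) == pytest.approx(0.75)

    def test_all_ones_chain(self, chain_graph):
        (circuit,) = extract_circuits(chain_graph)
        state = propagate_circuit(
            circuit, chain_graph, profile_of(R=1, A=1, E=1)
        )
        assert circuit_activity(circuit, state) == pytest.approx(1.0)

    def test_dead_receptor_silences_effector(self, chain_graph):
        (circuit,) = extract_circuits(chain_graph)
        state = propagate_circuit(
            circuit, chain_graph, profile_of(R=0, A=1, E=1)
        )
        assert circuit_activity(circuit, state) == pytest.approx(0.0)

    def test_outside_intervention_cannot_leak_in(self):
        # F is outside E's circuit; changing F must not move E's activity
        graph = simple_graph(
            [
                ("R", "A", "activation"),
                ("A", "E", "activation"),
                ("A", "F", "activation"),
            ]
        )
        circuits = {c.effector: c for c in extract_circuits(graph)}
        base = propagate_circuit(
            circuits["E"], graph, profile_of(R=1, A=0.6, E=0.8, F=0.9)
        )
        perturbed = propagate_circuit(
            circuits["E"], graph, profile_of(R=1, A=0.6, E=0.8, F=0.0)
        )
        assert circuit_activity(circuits["E"], base) == pytest.approx(
            circuit_activity(circuits["E"], perturbed)
        )

    def test_missing_effector_in_state_errors(self, chain_graph):
        (circuit,) = extract_circuits(chain_graph)
        from circuitsim import SignalState

        with pytest.raises(KeyError, match="effector"):
            circuit_activity(
                circuit, SignalState({"R": 1.0}, 1, True, 0.0)
            )
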