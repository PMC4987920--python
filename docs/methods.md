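# Methods

## The model

`circuitsim` treats a signaling pathway as a directed graph whose nodes
are gene products (or small groups of them) and whose edges are signed:
*activation* or *inhibition*. Two node classes anchor the biology:
**receptors** (no incoming edge) are where extracellular stimulus enters
the network, and **effectors** (no outgoing edge) are the proteins that
trigger the downstream cell response (apoptosis, proliferation,
angiogenesis, ...). A **signaling circuit** is the subgraph connecting one
effector back to every receptor from which it is reachable; the circuit is
the unit whose activity is computed, perturbed and compared.

Normalized gene expression values in [0, 1] are used directly as proxies
of gene activity — the probability that the gene's product is present and
functional. Signal intensity S_n at node n with own activity v_n follows

    S_n = v_n · (1 − ∏_{a∈act(n)} (1 − S_a)) · ∏_{i∈inh(n)} (1 − S_i)

read as three independent requirements: the node's product must be active
(v_n), at least one activating input must carry signal (a noisy-OR over
activating parents), and no inhibiting input may fire. A node with no
activating parents takes an activation factor of 1 — in particular a
receptor carries S = v, i.e. stimulus is assumed present at full strength
and the expression profile is the sole driver. A circuit's activity is its
effector's signal, computed **on the circuit subgraph** so that
perturbations outside the circuit cannot leak in except through member
nodes.

Interventions transform the profile before re-propagation:

- a **gene intervention** forces an absolute activity (0 = knock-out,
  1 = over-expression, anything between a partial intervention);
- a **drug action** multiplies each target gene's *original* activity by
  the drug's action weight (< 1 antagonist, 1 neutral, > 1 agonist) and
  clamps the result into [0, 1]. A weight of 0.1 therefore leaves the gene
  at 10% of its measured activity, not at an activity of 0.1.

Several drugs hitting the same gene compose by multiplying their weights
on the running value with a single final clamp, which makes multi-drug
application exactly commutative. Explicit gene interventions are applied
after drugs and override them on the same gene (stated user intent beats a
derived effect); duplicated forced values resolve last-write-wins with a
warning.

The simulated condition is compared to the reference by a symmetric
fold-change on epsilon-shifted activities, ratio = (sim + ε)/(ref + ε)
with ε = 1e-9: a circuit is *up* when the ratio reaches the threshold,
*down* when its reciprocal does, *unchanged* otherwise. The threshold
defaults to 2. Because a single sample offers no conventional testing
scenario, the threshold is a descriptive cutoff, not a significance
level, and no multiple-testing correction is applied.

## Numerical procedure

Acyclic pathways are solved exactly in one topological sweep. Pathways
with feedback loops are solved by synchronous (Jacobi) fixed-point
iteration starting from S = v, stopping when the largest per-node change
falls below `tolerance` (default 1e-6) or after `max_iterations`
(default 1000); non-convergence — possible for strongly inhibitory
loops, which can oscillate under synchronous updates — is flagged on the
returned state and logged, never raised. Synchronous updating was chosen
over damped or in-place (Gauss–Seidel) schemes because it is
deterministic and independent of node ordering. Note that the stopping
residual bounds the last step, not the distance to the fixed point: on
cyclic graphs with contraction factor ρ the remaining error can reach
roughly residual·ρ/(1−ρ), so callers comparing against an external
ground truth should tighten `tolerance` below the agreement they want.

The update rule maps [0, 1]ⁿ to itself, so signals can never leave the
unit interval regardless of topology or profile; on activation-only
graphs it is monotone in every input, and an inhibitor's rising signal
can only lower its direct target. These provable properties are also
exercised as randomized tests.

Other numerical choices: genes present in a pathway but missing from the
profile receive a neutral default activity of 0.5 (configurable), which
neither kills nor saturates passing signal; multi-gene *complex* nodes
pool member activities by minimum (every subunit required), *family* and
multi-gene simple nodes by mean; probe-level expression is collapsed to
genes by arithmetic mean (summed in sorted order, so the result is
exactly invariant to probe order); `rescale` validation mode applies a
min-max transform, with a constant profile mapped to 0.5 everywhere,
while the default `strict` mode refuses out-of-range values rather than
silently changing user data.

## Pathway input

The canonical interchange format is a tab-separated edge list
(`source  target  sign`) with an optional node table
(`node_id  gene_ids  node_class  [role]`). The `role` column pins
receptor/effector status explicitly, which is the only way to define
receptors in a graph where every node lies on a cycle; otherwise
classification is purely topological (in-degree 0 / out-degree 0, an
isolated node being both). A KGML (KEGG pathway XML) reader is provided,
import-only: `gene` entries become nodes (multi-gene entries as `family`
nodes), relation subtypes activation/expression map to activation and
inhibition/repression to inhibition, and everything else — compound and
map entries, group (complex) entries, phosphorylation-style subtypes,
relations touching skipped entries — is skipped with a logged count. No
pathway corpus is bundled and nothing is fetched from the network.

Circuit membership is computed by forward/backward reachability
(ancestors of the effector intersected with descendants of the
receptors) rather than by enumerating simple paths. On DAGs the two
definitions coincide — the test suite checks this exhaustively against a
brute-force path-enumeration oracle on small random graphs — while
reachability stays polynomial and well-defined in the presence of
feedback loops. Circuits are keyed by effector, so one circuit
aggregates all receptors feeding that effector.

## Synthetic data and what passing tests show

The fixture generator builds seeded random DAGs (optionally with one
added back-edge to create a feedback loop): nodes are ordered, forward
edges drawn independently with probability `edge_density` (default 0.4
on 8 nodes), each edge inhibitory with probability
`inhibition_fraction` (default 0.25), redrawing until weakly connected.
Profiles are uniform [0, 1] per gene. A single integer seed determines
every fixture; no global random state is used. These fixtures exercise
the propagation, extraction and comparison machinery across topologies,
but they do not emulate the degree distribution, edge-sign layout or
expression correlation structure of curated pathways — so green tests
certify the algorithmic contracts, not biological realism of any
particular prediction.

The test oracle for propagation is an independent dense-matrix
implementation of the same update rule, iterated synchronously with no
convergence test (it stops only when two consecutive states are bitwise
identical, after which further iterations provably cannot change the
result).

Problem sizes used by the automated checks: oracle agreement on 120
random graphs of 4–20 nodes (≥100 of them convergent) at 1e-6;
topological-sweep vs long-run iteration at 1e-9 on 30 DAGs; circuit
extraction vs brute-force path enumeration on 220 DAGs of 4–12 nodes;
end-to-end knock-out and identity runs on a generated two-pathway bundle
plus a hand-written bottleneck pathway.

## Known limitations

- The propagation model is the simplified expression-as-activity variant:
  no empirical activity distributions, no stochastic sampling of gene
  states, no mutation input.
- Receptor stimulus is assumed present at full strength; ligand
  availability is not modelled.
- Off-target drug effects are not predicted — only listed targets are
  touched; the packaged drug-target table contains a single worked entry
  (sorafenib) and users supply their own table for anything else.
- Non-convergent feedback loops are reported, not resolved; a damped
  scheme could force convergence but would introduce an arbitrary
  damping parameter.
- One sample per run; comparing groups of samples statistically is out
  of scope.
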