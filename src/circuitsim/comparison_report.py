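"""Compare simulated vs reference circuit activities and write reports.

The change in each circuit is summarized by a symmetric fold-change on
epsilon-shifted activities, ratio = (simulated + eps) / (reference +
eps); a circuit is labelled ``up`` when the ratio reaches the threshold
(default 2), ``down`` when its reciprocal does, ``unchanged`` otherwise.
The epsilon guard keeps circuits with zero reference activity finite and
makes the ratio exactly antisymmetric under swapping the two conditions.
There is no conventional testing scenario for a single sample, so the
threshold is a descriptive cutoff, not a significance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .circuit_extraction import Circuit

LABEL_UP = "up"
LABEL_DOWN = "down"
LABEL_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class ComparisonConfig:
    """Fold-change threshold (> 1) and zero-denominator guard."""

    threshold: float = 2.0
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.threshold <= 1:
            raise ValueError("threshold must be > 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class CircuitDelta:
    """One circuit's reference/simulated activity, fold-change and label."""

    circuit_id: str
    reference_activity: float
    simulated_activity: float
    ratio: float
    label: str


def compare(
    reference: dict[str, float],
    simulated: dict[str, float],
    config: ComparisonConfig | None = None,
) -> list[CircuitDelta]:
    """Label every circuit up/down/unchanged by symmetric fold-change.

    Both maps must share the same circuit-id key set.  Output is sorted
    with changed circuits first, by |log ratio| descending (ties broken
    by circuit id) so the strongest effects lead the report.
    """
    config = config or ComparisonConfig()
    if set(reference) != set(simulated):
        only_ref = sorted(set(reference) - set(simulated))
        only_sim = sorted(set(simulated) - set(reference))
        raise KeyError(
            "reference and simulated circuit ids differ; "
            f"only in reference: {only_ref}; only in simulated: {only_sim}"
        )
    deltas = []
    for circuit_id in reference:
        ref = reference[circuit_id]
        sim = simulated[circuit_id]
        ratio = (sim + config.epsilon) / (ref + config.epsilon)
        if ratio >= config.threshold:
            label = LABEL_UP
        elif 1.0 / ratio >= config.threshold:
            label = LABEL_DOWN
        else:
            label = LABEL_UNCHANGED
        deltas.append(CircuitDelta(circuit_id, ref, sim, ratio, label))
    deltas.sort(
        key=lambda d: (
            d.label == LABEL_UNCHANGED,
            -abs(math.log(d.ratio)),
            d.circuit_id,
        )
    )
    return deltas


def summarize_pathways(
    deltas: list[CircuitDelta], circuits: list[Circuit]
) -> dict[str, dict[str, int | bool]]:
    """Per-pathway tallies of up/down/unchanged circuits.

    A pathway is flagged when at least one of its circuits changed
    significantly.
    """
    pathway_of = {c.circuit_id: c.pathway_id for c in circuits}
    summary: dict[str, dict[str, int | bool]] = {}
    for delta in deltas:
        pathway_id = pathway_of.get(delta.circuit_id)
        if pathway_id is None:
            raise KeyError(
                f"circuit {delta.circuit_id!r} not found in the circuit catalog"
            )
        entry = summary.setdefault(
            pathway_id,
            {LABEL_UP: 0, LABEL_DOWN: 0, LABEL_UNCHANGED: 0, "flagged": False},
        )
        entry[delta.label] += 1
    for entry in summary.values():
        entry["flagged"] = bool(entry[LABEL_UP] or entry[LABEL_DOWN])
    return summary


def write_report(
    deltas: list[CircuitDelta],
    circuits: list[Circuit],
    path: str | Path,
) -> None:
    """Write the per-circuit comparison TSV (floats with 6 decimals)."""
    meta = {c.circuit_id: c for c in circuits}
    with open(path, "w") as fh:
        fh.write(
            "circuit_id\tpathway_id\teffector\treference_activity"
            "\tsimulated_activity\tratio\tlabel\n"
        )
        for d in deltas:
            c = meta[d.circuit_id]
            fh.write(
                f"{d.circuit_id}\t{c.pathway_id}\t{c.effector}"
                f"\t{d.reference_activity:.6f}\t{d.simulated_activity:.6f}"
                f"\t{d.ratio:.6f}\t{d.label}\n"
            )


def write_summary(
    summary: dict[str, dict[str, int | bool]], path: str | Path
) -> None:
    """Write the per-pathway summary TSV."""
    with open(path, "w") as fh:
        fh.write("pathway_id\tup\tdown\tunchanged\tflagged\n")
        for pathway_id in sorted(summary):
            entry = summary[pathway_id]
            fh.write(
                f"{pathway_id}\t{entry[LABEL_UP]}\t{entry[LABEL_DOWN]}"
                f"\t{entry[LABEL_UNCHANGED]}\t{'yes' if entry['flagged'] else 'no'}\n"
            )
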