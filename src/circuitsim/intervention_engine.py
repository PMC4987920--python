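"""Gene interventions and drug actions applied to an expression profile.

A gene intervention forces a gene's activity to an absolute value: 0
simulates a knock-out, 1 an over-expression, any intermediate value a
partial intervention.  A drug action instead scales each target gene's
*original* activity by the drug's action weight (< 1 antagonist, 1
neutral, > 1 agonist), with the result clamped into [0, 1].  Drugs
compose multiplicatively on the running value with a single final clamp,
so multi-drug application is exactly commutative; explicit gene
interventions are applied last and override any drug effect on the same
gene.

A small packaged drug-target table is included so the canonical
multi-kinase-inhibitor example (sorafenib, nine target genes) works out
of the box; it stands in for a live drug-target database lookup.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .expression_io import ExpressionProfile

logger = logging.getLogger(__name__)


class InterventionError(ValueError):
    """Raised for unknown drugs/genes or malformed intervention input."""


@dataclass(frozen=True)
class GeneIntervention:
    """Force one gene's activity to ``forced_activity`` (KO = 0, OE = 1)."""

    gene: str
    forced_activity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.forced_activity <= 1.0:
            raise InterventionError(
                f"forced activity for {self.gene!r} must lie in [0, 1], "
                f"got {self.forced_activity}"
            )


@dataclass(frozen=True)
class DrugAction:
    """A drug with its target genes and multiplicative action weight."""

    drug: str
    targets: tuple[str, ...]
    weight: float

    def __post_init__(self) -> None:
        if not self.targets:
            raise InterventionError(f"drug {self.drug!r} has no targets")
        if self.weight < 0:
            raise InterventionError(
                f"drug {self.drug!r}: weight must be non-negative"
            )


@dataclass
class InterventionSet:
    """Drug actions plus gene interventions applied together in one run."""

    gene_interventions: list[GeneIntervention] = field(default_factory=list)
    drug_actions: list[DrugAction] = field(default_factory=list)


def apply_drug(profile: ExpressionProfile, action: DrugAction) -> ExpressionProfile:
    """Scale each target gene's activity by the drug weight, clamped to 1.

    A weight of 0.1 leaves the gene at 10% of its original activity (not
    at an activity of 0.1); a weight of 0 zeroes it; agonist overshoot
    past 1 is trimmed to 1.  Target genes absent from the profile are
    left untouched with a warning, non-targets are never modified.
    """
    out = profile.copy()
    for gene in action.targets:
        if gene not in out.values:
            logger.warning(
                "drug %s: target %s not in the expression profile, skipped",
                action.drug,
                gene,
            )
            continue
        out.values[gene] = min(1.0, action.weight * out.values[gene])
    return out


def apply_gene_intervention(
    profile: ExpressionProfile,
    iv: GeneIntervention,
    pathway_genes: Optional[set[str]] = None,
) -> ExpressionProfile:
    """Replace one gene's activity with the forced value.

    A gene absent from the profile but present in a loaded pathway is
    added with the forced value; a gene known to neither is rejected as
    a likely typo (when ``pathway_genes`` is provided).
    """
    out = profile.copy()
    if iv.gene not in out.values:
        if pathway_genes is not None and iv.gene not in pathway_genes:
            raise InterventionError(
                f"gene {iv.gene!r} is neither in the expression profile nor "
                "in any loaded pathway (possible typo)"
            )
        logger.info(
            "gene %s absent from the profile; added with forced activity %.3g",
            iv.gene,
            iv.forced_activity,
        )
    out.values[iv.gene] = iv.forced_activity
    return out


def apply_all(
    profile: ExpressionProfile,
    interventions: InterventionSet,
    pathway_genes: Optional[set[str]] = None,
) -> ExpressionProfile:
    """Apply all drug actions, then all gene interventions.

    Drug weights act on the original profile values and compose
    multiplicatively per gene, with one final clamp into [0, 1] so the
    result is independent of drug order.  Gene interventions are absolute
    overrides and win over drug effects on the same gene; duplicate
    forced values for one gene resolve last-write-wins with a warning.
    """
    out = profile.copy()
    weight_product: dict[str, float] = {}
    for action in interventions.drug_actions:
        for gene in action.targets:
            if gene not in profile.values:
                logger.warning(
                    "drug %s: target %s not in the expression profile, skipped",
                    action.drug,
                    gene,
                )
                continue
            weight_product[gene] = weight_product.get(gene, 1.0) * action.weight
    for gene, w in weight_product.items():
        out.values[gene] = min(1.0, w * profile.values[gene])

    forced: dict[str, GeneIntervention] = {}
    for iv in interventions.gene_interventions:
        if iv.gene in forced and forced[iv.gene].forced_activity != iv.forced_activity:
            logger.warning(
                "conflicting forced activities for %s; keeping the last (%.3g)",
                iv.gene,
                iv.forced_activity,
            )
        forced[iv.gene] = iv
    for iv in forced.values():
        if iv.gene in weight_product:
            logger.warning(
                "gene intervention on %s overrides a drug effect on the same gene",
                iv.gene,
            )
        out = apply_gene_intervention(out, iv, pathway_genes)
    return out


def load_drug_table(path: str | Path) -> dict[str, DrugAction]:
    """Load a drug-target TSV ``drug  target_gene  default_weight``.

    One row per (drug, target); the weight column is optional and
    defaults to 0 (full target knock-out).  Keys are lower-cased drug
    names.
    """
    rows: dict[str, tuple[list[str], float, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0].lower() == "drug":
                continue
            if len(fields) < 2:
                raise InterventionError(
                    f"{path}:{lineno}: expected at least 2 columns "
                    "(drug, target_gene)"
                )
            drug = fields[0].strip()
            gene = fields[1].strip()
            weight = 0.0
            if len(fields) > 2 and fields[2].strip():
                try:
                    weight = float(fields[2])
                except ValueError:
                    raise InterventionError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
            key = drug.lower()
            if key not in rows:
                rows[key] = ([], weight, drug)
            rows[key][0].append(gene)
    return {
        key: DrugAction(name, tuple(targets), weight)
        for key, (targets, weight, name) in rows.items()
    }


def default_drug_table() -> dict[str, DrugAction]:
    """The packaged drug-target table (currently the sorafenib target set)."""
    with resources.as_file(
        resources.files("circuitsim.data") / "sorafenib_targets.tsv"
    ) as path:
        return load_drug_table(path)


def lookup_drug(
    drug: str, table: Optional[dict[str, DrugAction]] = None
) -> DrugAction:
    """Case-insensitive drug lookup; unknown names report near-matches."""
    if table is None:
        table = default_drug_table()
    action = table.get(drug.lower())
    if action is None:
        close = difflib.get_close_matches(drug.lower(), table.keys(), n=3)
        hint = f" (did you mean: {', '.join(close)}?)" if close else ""
        raise InterventionError(f"unknown drug {drug!r}{hint}")
    return action


def load_interventions(path: str | Path) -> list[GeneIntervention]:
    """Load a gene-intervention TSV ``gene  forced_activity``."""
    interventions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0].lower() == "gene":
                continue
            if len(fields) < 2:
                raise InterventionError(
                    f"{path}:{lineno}: expected 2 columns (gene, forced_activity)"
                )
            try:
                value = float(fields[1])
            except ValueError:
                raise InterventionError(
                    f"{path}:{lineno}: non-numeric forced activity {fields[1]!r}"
                ) from None
            interventions.append(GeneIntervention(fields[0].strip(), value))
    return interventions
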