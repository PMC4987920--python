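"""Expression-profile input: parsing, probe aggregation, range validation.

Normalized gene expression values in [0, 1] are used directly as proxies
of gene activity.  Input is a plain text table: identifier column plus
one or more sample columns; microarray probe identifiers are collapsed
to genes by arithmetic mean over all probes mapping to each gene.
Normalization itself is delegated upstream — ``strict`` mode (the
default) refuses out-of-range values rather than silently transforming
user data, while ``rescale`` mode applies a min-max transform as a
convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Raised on malformed or out-of-range expression input."""


@dataclass
class ExpressionProfile:
    """One sample's gene -> activity map, activities in [0, 1]."""

    sample_id: str
    values: dict[str, float]
    provenance: Optional[dict[str, list[str]]] = None

    def copy(self) -> "ExpressionProfile":
        return ExpressionProfile(
            self.sample_id,
            dict(self.values),
            None if self.provenance is None else {
                g: list(p) for g, p in self.provenance.items()
            },
        )


def _parse_rows(path: Path) -> tuple[list[str], list[tuple[int, str, list[float]]]]:
    """Parse the raw table; returns (sample column names, data rows).

    Rows are (line number, identifier, values).  A header is assumed when
    the first non-comment line has no parseable number in column 2.
    """
    raw_rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ExpressionError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}"
                )
            raw_rows.append((lineno, fields))
    if not raw_rows:
        raise ExpressionError(f"{path}: no data rows found")

    def _is_numeric(token: str) -> bool:
        try:
            float(token)
            return True
        except ValueError:
            return False

    # the first row is a header when its value columns are non-numeric and
    # data rows follow; a lone unparseable row is a data error, not a header
    header: list[str] = []
    if len(raw_rows) > 1 and not _is_numeric(raw_rows[0][1][1]):
        header = [f.strip() for f in raw_rows[0][1][1:]]
        raw_rows = raw_rows[1:]

    rows: list[tuple[int, str, list[float]]] = []
    for lineno, fields in raw_rows:
        try:
            values = [float(f) for f in fields[1:]]
        except ValueError:
            raise ExpressionError(
                f"{path}:{lineno}: non-numeric expression value in "
                f"row {fields[0]!r}"
            ) from None
        rows.append((lineno, fields[0].strip(), values))
    n_samples = len(rows[0][2])
    for lineno, ident, values in rows:
        if len(values) != n_samples:
            raise ExpressionError(
                f"{path}:{lineno}: ragged row ({len(values)} values, "
                f"expected {n_samples})"
            )
    if not header:
        header = [f"S{i + 1}" for i in range(n_samples)]
    return header, rows


def read_probe_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV ``probe  gene``; many-to-many mappings allowed."""
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                continue
            if fields[0].lower() == "probe" and fields[1].lower() == "gene":
                continue
            mapping.setdefault(fields[0].strip(), []).append(fields[1].strip())
    return mapping


def aggregate_probes(
    rows: list[tuple[str, float]],
    probe_map: dict[str, list[str]],
) -> dict[str, float]:
    """Collapse probe-level values to one activity per gene.

    Each gene's value is the arithmetic mean over all probes mapping to
    it; a probe may contribute to several genes.  Probes without a
    mapping are dropped with a logged count; an empty intersection of
    probes and map is an error.
    """
    per_gene: dict[str, list[float]] = {}
    unmapped = 0
    for probe, value in rows:
        genes = probe_map.get(probe)
        if not genes:
            unmapped += 1
            continue
        for gene in genes:
            per_gene.setdefault(gene, []).append(value)
    if unmapped:
        logger.info("dropped %d probes with no gene mapping", unmapped)
    if not per_gene:
        raise ExpressionError(
            "no probe in the expression file matches the probe map"
        )
    # summing in sorted order makes the mean exactly probe-order invariant
    return {
        gene: sum(sorted(values)) / len(values)
        for gene, values in per_gene.items()
    }


def validate_range(
    profile: ExpressionProfile, mode: str = "strict"
) -> ExpressionProfile:
    """Enforce activities in [0, 1].

    ``strict`` raises naming every offending gene; ``rescale`` applies a
    min-max transform x -> (x - min) / (max - min) across the profile.  A
    constant profile cannot be rescaled and is set to 0.5 everywhere with
    a warning.
    """
    if mode == "strict":
        bad = sorted(g for g, v in profile.values.items() if not 0.0 <= v <= 1.0)
        if bad:
            raise ExpressionError(
                "activities outside [0, 1] for genes: "
                + ", ".join(bad[:20])
                + ("..." if len(bad) > 20 else "")
                + " (use rescale mode to min-max transform)"
            )
        return profile
    if mode == "rescale":
        vals = profile.values
        lo, hi = min(vals.values()), max(vals.values())
        if hi == lo:
            logger.warning(
                "constant expression profile cannot be min-max rescaled; "
                "all activities set to 0.5"
            )
            scaled = {g: 0.5 for g in vals}
        else:
            scaled = {g: (v - lo) / (hi - lo) for g, v in vals.items()}
        return ExpressionProfile(profile.sample_id, scaled, profile.provenance)
    raise ValueError(f"unknown validation mode {mode!r}")


def read_expression(
    file: str | Path,
    sample: Optional[str] = None,
    probe_map: Optional[dict[str, list[str]]] = None,
    mode: str = "strict",
) -> ExpressionProfile:
    """Read one sample's expression profile from a text table.

    With more than two columns, ``sample`` selects the column to analyze
    (one sample per run).  If ``probe_map`` is given, identifiers are
    treated as probes and aggregated to genes; otherwise duplicate gene
    rows are averaged with a warning.  Values are range-validated per
    ``mode`` before being returned.
    """
    path = Path(file)
    header, rows = _parse_rows(path)
    if len(header) == 1:
        col = 0
        sample_id = sample or header[0]
    else:
        if sample is None:
            raise ExpressionError(
                f"{path}: multiple sample columns found; choose one of: "
                + ", ".join(header)
            )
        if sample not in header:
            raise ExpressionError(
                f"{path}: no sample column {sample!r}; available: "
                + ", ".join(header)
            )
        col = header.index(sample)
        sample_id = sample

    pairs = [(ident, values[col]) for _, ident, values in rows]
    provenance: Optional[dict[str, list[str]]] = None
    if probe_map is not None:
        values = aggregate_probes(pairs, probe_map)
        provenance = {}
        for probe, _ in pairs:
            for gene in probe_map.get(probe, []):
                provenance.setdefault(gene, []).append(probe)
    else:
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for gene, value in pairs:
            sums[gene] = sums.get(gene, 0.0) + value
            counts[gene] = counts.get(gene, 0) + 1
        dupes = sorted(g for g, c in counts.items() if c > 1)
        if dupes:
            logger.warning(
                "averaged %d duplicated gene identifiers (e.g. %s)",
                len(dupes),
                ", ".join(dupes[:5]),
            )
        values = {g: sums[g] / counts[g] for g in sums}

    profile = ExpressionProfile(sample_id, values, provenance)
    return validate_range(profile, mode=mode)
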