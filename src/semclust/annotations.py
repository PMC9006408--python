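"""Gene-to-term annotation tables with true-path closure.

A gene annotated to a term is implicitly annotated to all of the term's
ancestors; closing the table once at load time lets conjunction-coverage
queries work by plain set intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .ontology import OntologyGraph

__all__ = [
    "AnnotationError",
    "AnnotationTable",
    "load_annotations",
    "load_gaf",
    "propagate_true_path",
    "genes_with_all_terms",
]

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Annotation input unusable (empty, or mostly unmapped terms)."""


@dataclass(frozen=True)
class AnnotationTable:
    """Immutable gene <-> term incidence over a fixed gene universe.

    ``closed`` records whether true-path propagation has been applied.
    """

    pairs: frozenset[tuple[str, str]]
    gene_universe: frozenset[str]
    closed: bool = False
    dropped_unknown_terms: int = 0
    dropped_foreign_genes: int = 0
    _term_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        index: dict[str, set[str]] = {}
        for gene, term in self.pairs:
            if gene not in self.gene_universe:
                raise AnnotationError(
                    f"annotation pair references gene {gene!r} outside the universe"
                )
            index.setdefault(term, set()).add(gene)
        object.__setattr__(
            self, "_term_index", {t: frozenset(g) for t, g in index.items()}
        )

    @property
    def term_ids(self) -> frozenset[str]:
        return frozenset(self._term_index)

    def genes_for_term(self, term_id: str) -> frozenset[str]:
        return self._term_index.get(term_id, frozenset())

    def terms_for_gene(self, gene_id: str) -> frozenset[str]:
        return frozenset(t for g, t in self.pairs if g == gene_id)

    def __len__(self) -> int:
        return len(self.pairs)


def _build_table(
    rows: Iterable[tuple[str, str]],
    graph: OntologyGraph,
    universe: Iterable[str],
    source: str,
) -> AnnotationTable:
    universe = frozenset(universe)
    rows = list(rows)
    if not rows:
        raise AnnotationError(f"{source}: no annotation rows found")
    unknown = 0
    foreign = 0
    pairs: set[tuple[str, str]] = set()
    for gene, term in rows:
        if term not in graph:
            unknown += 1
            continue
        if gene not in universe:
            foreign += 1
            continue
        pairs.add((gene, term))
    if unknown > len(rows) / 2:
        raise AnnotationError(
            f"{source}: {unknown}/{len(rows)} rows reference unknown terms; "
            "likely the wrong ontology was supplied"
        )
    if unknown:
        log.warning("%s: dropped %d rows with unknown terms", source, unknown)
    if foreign:
        log.warning(
            "%s: dropped %d rows for genes outside the universe", source, foreign
        )
    return AnnotationTable(
        pairs=frozenset(pairs),
        gene_universe=universe,
        closed=False,
        dropped_unknown_terms=unknown,
        dropped_foreign_genes=foreign,
    )


def load_annotations(
    path: str | Path,
    graph: OntologyGraph,
    universe: Iterable[str],
    *,
    close: bool = True,
) -> AnnotationTable:
    """Read a two-column (gene_id, term_id) TSV.

    A header line is tolerated: if the first line's second column does not
    resolve in ``graph`` and its first column is outside the universe, it is
    treated as a header.  Rows with unmapped terms are dropped with a logged
    warning count; if more than half the rows are unmapped the load fails.
    """
    path = Path(path)
    universe = frozenset(universe)
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise AnnotationError(
                    f"{path.name}:{lineno}: expected two columns, got {line!r}"
                )
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows and rows[0][1] not in graph and rows[0][0] not in universe:
        rows = rows[1:]  # header
    table = _build_table(rows, graph, universe, path.name)
    return propagate_true_path(table, graph) if close else table


def load_gaf(
    path: str | Path,
    graph: OntologyGraph,
    universe: Iterable[str],
    *,
    close: bool = True,
) -> AnnotationTable:
    """Convenience GAF 2.x reader using the symbol and ontology-id columns."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            rows.append((fields[2].strip(), fields[4].strip()))
    table = _build_table(rows, graph, frozenset(universe), path.name)
    return propagate_true_path(table, graph) if close else table


def propagate_true_path(
    table: AnnotationTable, graph: OntologyGraph
) -> AnnotationTable:
    """Close the table: every (gene, term) implies (gene, ancestor) pairs.

    Idempotent; never removes pairs.
    """
    closed: set[tuple[str, str]] = set()
    for gene, term in table.pairs:
        for anc in graph.ancestors(term):
            closed.add((gene, anc))
    return AnnotationTable(
        pairs=frozenset(closed),
        gene_universe=table.gene_universe,
        closed=True,
        dropped_unknown_terms=table.dropped_unknown_terms,
        dropped_foreign_genes=table.dropped_foreign_genes,
    )


def genes_with_all_terms(
    table: AnnotationTable, term_ids: Iterable[str]
) -> frozenset[str]:
    """Genes annotated to every term in ``term_ids`` (conjunction coverage)."""
    term_ids = list(term_ids)
    if not term_ids:
        raise ValueError("genes_with_all_terms requires a non-empty term set")
    covered = table.genes_for_term(term_ids[0])
    for tid in term_ids[1:]:
        covered = covered & table.genes_for_term(tid)
        if not covered:
            break
    return frozenset(covered)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    """Write the (gene, term) pairs as a sorted two-column TSV."""
    lines = ["gene_id\tterm_id"]
    for gene, term in sorted(table.pairs):
        lines.append(f"{gene}\t{term}")
    Path(path).write_text("\n".join(lines) + "\n")
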