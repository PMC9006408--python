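"""Ontology DAGs: OBO parsing, ancestry queries and term specificity levels.

The graph stores parent edges only (child -> parents).  ``is_a`` and
``relationship: part_of`` are both treated as parent edges by default, since
annotation propagation conventionally follows both; a switch restricts the
load to ``is_a`` when needed.  Terms flagged obsolete are dropped at parse
time.  Levels are shortest-path distances to a root (a term with no parents),
so every root sits at level 0 even after merging several source ontologies.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "OboParseError",
    "OntologyStructureError",
    "OntologyTerm",
    "OntologyGraph",
    "load_obo",
    "merge",
    "ancestors",
    "term_level",
]


class OboParseError(ValueError):
    """A [Term] stanza could not be interpreted."""


class OntologyStructureError(ValueError):
    """The parsed term set does not form a valid DAG."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term with its direct parents."""

    term_id: str
    name: str
    namespace: str
    parent_ids: tuple[str, ...]


class OntologyGraph:
    """Immutable DAG of :class:`OntologyTerm` keyed by term id.

    Construction validates that every parent id resolves and that the parent
    relation is acyclic; ancestor sets and levels are computed lazily and
    cached.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self._terms: dict[str, OntologyTerm] = dict(terms)
        for tid, term in self._terms.items():
            if term.term_id != tid:
                raise OntologyStructureError(
                    f"term keyed as {tid!r} carries id {term.term_id!r}"
                )
            for pid in term.parent_ids:
                if pid not in self._terms:
                    raise OntologyStructureError(
                        f"term {tid!r} references unknown parent {pid!r}"
                    )
        self._assert_acyclic()
        self._roots = frozenset(
            tid for tid, t in self._terms.items() if not t.parent_ids
        )
        if self._terms and not self._roots:
            raise OntologyStructureError("graph has terms but no roots")
        self._children: dict[str, list[str]] = {tid: [] for tid in self._terms}
        for tid, term in self._terms.items():
            for pid in term.parent_ids:
                self._children[pid].append(tid)
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._levels: dict[str, int] | None = None

    # -- container protocol -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise KeyError(f"unknown ontology term {term_id!r}") from None

    @property
    def terms(self) -> Mapping[str, OntologyTerm]:
        return dict(self._terms)

    @property
    def roots(self) -> frozenset[str]:
        return self._roots

    def children(self, term_id: str) -> tuple[str, ...]:
        self[term_id]
        return tuple(self._children[term_id])

    def parents(self, term_id: str) -> tuple[str, ...]:
        return self[term_id].parent_ids

    # -- queries ------------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive closure over parent edges."""
        if term_id not in self._terms:
            raise KeyError(f"unknown ontology term {term_id!r}")
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [term_id]
        while stack:
            tid = stack.pop()
            if tid in out:
                continue
            out.add(tid)
            hit = self._ancestor_cache.get(tid)
            if hit is not None:
                out.update(hit)
                continue
            stack.extend(self._terms[tid].parent_ids)
        result = frozenset(out)
        self._ancestor_cache[term_id] = result
        return result

    def term_level(self, term_id: str) -> int:
        """Shortest parent-edge distance to any root; roots are level 0."""
        if term_id not in self._terms:
            raise KeyError(f"unknown ontology term {term_id!r}")
        if self._levels is None:
            self._levels = self._compute_levels()
        return self._levels[term_id]

    def max_level(self) -> int:
        if not self._terms:
            return 0
        return max(self.term_level(t) for t in self._terms)

    def merge(self, other: "OntologyGraph") -> "OntologyGraph":
        """Disjoint union; duplicated term ids are an error."""
        clash = set(self._terms) & set(other._terms)
        if clash:
            sample = sorted(clash)[:5]
            raise OntologyStructureError(
                f"cannot merge: {len(clash)} duplicate term ids, e.g. {sample}"
            )
        combined = dict(self._terms)
        combined.update(other._terms)
        return OntologyGraph(combined)

    # -- internals ----------------------------------------------------------

    def _assert_acyclic(self) -> None:
        # Kahn's algorithm over parent edges; leftovers imply a cycle.
        indeg = {tid: len(t.parent_ids) for tid, t in self._terms.items()}
        kids: dict[str, list[str]] = {tid: [] for tid in self._terms}
        for tid, term in self._terms.items():
            for pid in term.parent_ids:
                kids[pid].append(tid)
        queue = deque(tid for tid, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            tid = queue.popleft()
            seen += 1
            for kid in kids[tid]:
                indeg[kid] -= 1
                if indeg[kid] == 0:
                    queue.append(kid)
        if seen != len(self._terms):
            stuck = sorted(tid for tid, d in indeg.items() if d > 0)[:5]
            raise OntologyStructureError(
                f"cyclic parent closure involving terms such as {stuck}"
            )

    def _compute_levels(self) -> dict[str, int]:
        levels = {tid: 0 for tid in self._roots}
        queue = deque(self._roots)
        while queue:
            tid = queue.popleft()
            for kid in self._children[tid]:
                cand = levels[tid] + 1
                if kid not in levels or cand < levels[kid]:
                    levels[kid] = cand
                    queue.append(kid)
        return levels


# -- OBO parsing -------------------------------------------------------------


def _parse_stanzas(text: str):
    """Yield (header_lines, list of (stanza_type, lines, first_lineno))."""
    header: list[str] = []
    stanzas: list[tuple[str, list[str], int]] = []
    current: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("[") and line.endswith("]"):
            current = []
            stanzas.append((line[1:-1], current, lineno))
            continue
        if not line or line.startswith("!"):
            continue
        if current is None:
            header.append(line)
        else:
            current.append(line)
    return header, stanzas


def _tag_value(line: str) -> tuple[str, str]:
    tag, _, value = line.partition(":")
    # trailing OBO comments start with " ! "
    value = value.split(" ! ")[0].strip()
    if value.endswith("!"):
        value = value[:-1].strip()
    return tag.strip(), value


def load_obo(
    path: str | Path,
    *,
    include_part_of: bool = True,
    namespace: str | None = None,
) -> OntologyGraph:
    """Parse an OBO flat file into an :class:`OntologyGraph`.

    Parameters
    ----------
    path:
        OBO-format text file with ``[Term]`` stanzas.
    include_part_of:
        When true (default) ``relationship: part_of`` lines contribute parent
        edges alongside ``is_a``.
    namespace:
        Fallback namespace for terms lacking a ``namespace`` tag; defaults to
        the file's ``default-namespace`` header or the file stem.
    """
    path = Path(path)
    text = path.read_text()
    header, stanzas = _parse_stanzas(text)

    default_ns = namespace
    if default_ns is None:
        for line in header:
            tag, value = _tag_value(line)
            if tag == "default-namespace":
                default_ns = value
                break
    if default_ns is None:
        default_ns = path.stem

    terms: dict[str, OntologyTerm] = {}
    obsolete: set[str] = set()
    for stanza_type, lines, lineno in stanzas:
        if stanza_type != "Term":
            continue
        tid: str | None = None
        name = ""
        ns = default_ns
        parents: list[str] = []
        is_obsolete = False
        for line in lines:
            tag, value = _tag_value(line)
            if tag == "id":
                tid = value
            elif tag == "name":
                name = value
            elif tag == "namespace":
                ns = value
            elif tag == "is_a":
                parents.append(value)
            elif tag == "relationship" and include_part_of:
                rel, _, target = value.partition(" ")
                if rel.strip() == "part_of" and target.strip():
                    parents.append(target.strip())
            elif tag == "is_obsolete" and value.lower() == "true":
                is_obsolete = True
        if tid is None or not tid:
            raise OboParseError(
                f"{path.name}: [Term] stanza at line {lineno} has no id"
            )
        if is_obsolete:
            obsolete.add(tid)
            continue
        if tid in terms:
            raise OboParseError(
                f"{path.name}: duplicate term id {tid!r} at line {lineno}"
            )
        terms[tid] = OntologyTerm(
            term_id=tid,
            name=name,
            namespace=ns,
            parent_ids=tuple(dict.fromkeys(parents)),
        )

    # drop parent links that point at obsolete terms
    if obsolete:
        terms = {
            tid: OntologyTerm(
                term_id=t.term_id,
                name=t.name,
                namespace=t.namespace,
                parent_ids=tuple(p for p in t.parent_ids if p not in obsolete),
            )
            for tid, t in terms.items()
        }
    return OntologyGraph(terms)


def merge(*graphs: OntologyGraph) -> OntologyGraph:
    """Disjoint union of several graphs (duplicate ids raise)."""
    if not graphs:
        return OntologyGraph({})
    out = graphs[0]
    for g in graphs[1:]:
        out = out.merge(g)
    return out


def ancestors(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    """Reflexive-transitive parent closure of ``term_id``."""
    return graph.ancestors(term_id)


def term_level(graph: OntologyGraph, term_id: str) -> int:
    """Shortest parent-path length from ``term_id`` to any root."""
    return graph.term_level(term_id)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph back to minimal OBO (id/name/namespace/is_a)."""
    lines = ["format-version: 1.2", ""]
    for tid in sorted(graph):
        term = graph[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.term_id}")
        lines.append(f"name: {term.name}")
        lines.append(f"namespace: {term.namespace}")
        for pid in term.parent_ids:
            lines.append(f"is_a: {pid}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
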