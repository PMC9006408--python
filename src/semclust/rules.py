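"""Conjunctive ontology-term rule induction over a significance labeling.

A rule is a conjunction of ontology terms; a gene satisfies it iff the
(true-path-closed) annotation table links the gene to every term.  Rules are
scored against the significant/non-significant split of a labeling and
searched top-down with a deterministic beam: seeds are all eligible
single-term rules, refinements either add a non-redundant term or specialize
one term into a child.  No term in a rule may be an ancestor of another
(post-closure such a conjunct is redundant), and every term must sit at or
below the configured minimum specificity level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotations import AnnotationTable, genes_with_all_terms
from .diffexpr import ComparisonLabeling
from .ontology import OntologyGraph

__all__ = [
    "Rule",
    "RuleScore",
    "SearchConfig",
    "RuleContractError",
    "evaluate_rule",
    "refine",
    "induce_rules",
    "enforce_min_level",
]

log = logging.getLogger(__name__)

EVAL_FNS = ("ACC", "AUC", "F1")


class RuleContractError(ValueError):
    """Rule violates the redundancy or minimum-level contract."""


@dataclass(frozen=True, order=True)
class Rule:
    """Conjunction of ontology term ids (sorted, duplicate-free)."""

    term_ids: tuple[str, ...]

    def __init__(self, term_ids: Iterable[str]):
        terms = tuple(sorted(set(term_ids)))
        if not terms:
            raise RuleContractError("a rule needs at least one term")
        object.__setattr__(self, "term_ids", terms)

    def __len__(self) -> int:
        return len(self.term_ids)

    def __str__(self) -> str:
        return " AND ".join(self.term_ids)


def validate_rule(
    rule: Rule, graph: OntologyGraph, min_level: int = 0
) -> None:
    """Raise :class:`RuleContractError` on redundant or too-general rules."""
    for tid in rule.term_ids:
        if tid not in graph:
            raise RuleContractError(f"rule term {tid!r} not in ontology")
        if graph.term_level(tid) < min_level:
            raise RuleContractError(
                f"term {tid!r} at level {graph.term_level(tid)} "
                f"is above min_level {min_level}"
            )
    for tid in rule.term_ids:
        anc = graph.ancestors(tid) - {tid}
        redundant = anc & set(rule.term_ids)
        if redundant:
            raise RuleContractError(
                f"term(s) {sorted(redundant)} are ancestors of {tid!r} "
                "in the same rule"
            )


@dataclass(frozen=True)
class RuleScore:
    """Confusion counts and scores of a rule vs a labeling.

    Positive class = significant genes; ``covered`` = genes satisfying the
    conjunction.  ``auc`` is the balanced accuracy (mean of sensitivity and
    specificity), the AUC of a single Boolean predictor.
    """

    covered: frozenset[str]
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def acc(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def auc(self) -> float:
        sens = self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0
        spec = self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 0.0
        return 0.5 * (sens + spec)

    def value(self, eval_fn: str) -> float:
        fn = eval_fn.upper()
        if fn not in EVAL_FNS:
            raise ValueError(f"unknown eval fn {eval_fn!r}; expected {EVAL_FNS}")
        return {"ACC": self.acc, "AUC": self.auc, "F1": self.f1}[fn]

    @classmethod
    def from_cover(
        cls, covered: frozenset[str], significant: frozenset[str],
        universe: frozenset[str],
    ) -> "RuleScore":
        tp = len(covered & significant)
        fp = len(covered) - tp
        fn = len(significant) - tp
        tn = len(universe) - tp - fp - fn
        return cls(covered=covered, tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class SearchConfig:
    """Beam-search parameters for rule induction."""

    eval_fn: str = "F1"
    min_level: int = 0
    max_rules: int = 10
    max_conjuncts: int = 3
    beam_width: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.eval_fn.upper() not in EVAL_FNS:
            raise ValueError(f"eval_fn must be one of {EVAL_FNS}")
        if self.max_rules < 1:
            raise ValueError("max_rules must be >= 1")
        if self.beam_width < self.max_rules:
            raise ValueError("beam_width must be >= max_rules")
        if self.min_level < 0 or self.max_conjuncts < 1:
            raise ValueError("min_level >= 0 and max_conjuncts >= 1 required")
        object.__setattr__(self, "eval_fn", self.eval_fn.upper())


def evaluate_rule(
    rule: Rule,
    labeling: ComparisonLabeling,
    annotations: AnnotationTable,
    *,
    graph: OntologyGraph | None = None,
    min_level: int = 0,
) -> RuleScore:
    """Score a rule against a labeling; optionally verify its contract."""
    if graph is not None:
        validate_rule(rule, graph, min_level)
    covered = genes_with_all_terms(annotations, rule.term_ids)
    covered = covered & labeling.universe
    return RuleScore.from_cover(covered, labeling.significant_genes,
                                labeling.universe)


def enforce_min_level(
    term_ids: Iterable[str], graph: OntologyGraph, min_level: int
) -> frozenset[str]:
    """Subset of ``term_ids`` with specificity level >= ``min_level``."""
    return frozenset(
        t for t in term_ids if graph.term_level(t) >= min_level
    )


def _is_redundant(terms: Sequence[str], graph: OntologyGraph) -> bool:
    term_set = set(terms)
    for tid in terms:
        if (graph.ancestors(tid) - {tid}) & term_set:
            return True
    return False


def refine(
    rule: Rule,
    graph: OntologyGraph,
    candidate_terms: Iterable[str],
    *,
    max_conjuncts: int = 3,
    min_level: int = 0,
) -> list[Rule]:
    """Refinements: add one non-redundant candidate term, or replace one term
    by one of its children.  All outputs respect min_level and
    non-redundancy."""
    candidates = enforce_min_level(candidate_terms, graph, min_level)
    out: list[Rule] = []
    seen: set[tuple[str, ...]] = set()
    if len(rule) < max_conjuncts:
        for tid in sorted(candidates - set(rule.term_ids)):
            terms = rule.term_ids + (tid,)
            if _is_redundant(terms, graph):
                continue
            cand = Rule(terms)
            if cand.term_ids not in seen:
                seen.add(cand.term_ids)
                out.append(cand)
    for tid in rule.term_ids:
        rest = tuple(t for t in rule.term_ids if t != tid)
        for child in sorted(graph.children(tid)):
            if child not in candidates or child in rest:
                continue
            terms = rest + (child,)
            if _is_redundant(terms, graph):
                continue
            cand = Rule(terms)
            if cand.term_ids not in seen:
                seen.add(cand.term_ids)
                out.append(cand)
    return out


def _sort_key(entry: tuple[Rule, RuleScore], eval_fn: str):
    rule, score = entry
    return (-score.value(eval_fn), len(rule), rule.term_ids)


def _dedup_coverage(
    entries: list[tuple[Rule, RuleScore]], eval_fn: str
) -> list[tuple[Rule, RuleScore]]:
    """Collapse rules with identical covered sets (fewest conjuncts wins)."""
    best: dict[frozenset[str], tuple[Rule, RuleScore]] = {}
    for rule, score in sorted(entries, key=lambda e: _sort_key(e, eval_fn)):
        key = score.covered
        if key not in best:
            best[key] = (rule, score)
    return sorted(best.values(), key=lambda e: _sort_key(e, eval_fn))


def induce_rules(
    labeling: ComparisonLabeling,
    annotations: AnnotationTable,
    graph: OntologyGraph,
    config: SearchConfig = SearchConfig(),
) -> list[tuple[Rule, RuleScore]]:
    """Deterministic greedy beam search for discriminative conjunctions.

    Seeds with every eligible single-term rule, then repeatedly refines the
    beam, keeping the ``beam_width`` best by the configured evaluation
    function (ties: fewer conjuncts, then lexicographically smallest term
    tuple).  Stops when a refinement round leaves the beam unchanged or the
    conjunct limit is reached.  Returns at most ``max_rules``
    coverage-distinct rules sorted best-first; the best returned score can
    never fall below the best single-term seed.
    """
    if not labeling.universe:
        raise ValueError("empty gene universe")
    if not labeling.significant_genes or not labeling.nonsignificant_genes:
        raise ValueError(
            "labeling must contain both significant and non-significant genes"
        )
    annotated_terms = {
        t for t in annotations.term_ids
        if annotations.genes_for_term(t) & labeling.universe
    }
    candidates = enforce_min_level(annotated_terms, graph, config.min_level)
    if not candidates:
        log.warning(
            "no candidate terms at min_level=%d; returning no rules",
            config.min_level,
        )
        return []

    sig = labeling.significant_genes
    universe = labeling.universe

    def score_of(rule: Rule) -> RuleScore:
        covered = genes_with_all_terms(annotations, rule.term_ids) & universe
        return RuleScore.from_cover(covered, sig, universe)

    evaluated: dict[tuple[str, ...], RuleScore] = {}

    def consider(rule: Rule) -> tuple[Rule, RuleScore]:
        if rule.term_ids not in evaluated:
            evaluated[rule.term_ids] = score_of(rule)
        return rule, evaluated[rule.term_ids]

    beam = [consider(Rule([t])) for t in sorted(candidates)]
    beam.sort(key=lambda e: _sort_key(e, config.eval_fn))
    beam = beam[: config.beam_width]

    for _ in range(config.max_conjuncts - 1):
        fresh: list[tuple[Rule, RuleScore]] = []
        for rule, _score in beam:
            for cand in refine(
                rule, graph, candidates,
                max_conjuncts=config.max_conjuncts,
                min_level=config.min_level,
            ):
                if cand.term_ids not in evaluated:
                    fresh.append(consider(cand))
        if not fresh:
            break
        merged = sorted(beam + fresh, key=lambda e: _sort_key(e, config.eval_fn))
        new_beam = merged[: config.beam_width]
        if [r.term_ids for r, _ in new_beam] == [r.term_ids for r, _ in beam]:
            break
        beam = new_beam

    pool = [(Rule(t), s) for t, s in evaluated.items()]
    deduped = _dedup_coverage(pool, config.eval_fn)
    return deduped[: config.max_rules]
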