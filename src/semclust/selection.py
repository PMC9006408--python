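"""Pool rule-induction runs over a parameter grid and rank the survivors.

The grid crosses the pairwise comparisons with the evaluation functions and
minimum-level settings; pooled entries are deduplicated on (comparison,
covered gene set) with full provenance.  Ranking keeps rules whose covered
set contains at least ``min_difference`` more significant than
non-significant genes, sorted by a Welch t statistic contrasting the
comparison's per-gene expression difference between covered and uncovered
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotations import AnnotationTable
from .diffexpr import ComparisonLabeling, ExpressionTable
from .ontology import OntologyGraph
from .rules import Rule, RuleScore, SearchConfig, induce_rules

__all__ = [
    "PoolEntry",
    "RulePool",
    "SelectedRule",
    "run_grid",
    "select_rules",
]

log = logging.getLogger(__name__)

DEFAULT_EVAL_FNS = ("ACC", "AUC", "F1")
DEFAULT_MIN_LEVELS = (0, 2, 3, 4, 5, 6)


@dataclass
class PoolEntry:
    rule: Rule
    score: RuleScore
    comparison: tuple[str, str]
    provenance: list[SearchConfig] = field(default_factory=list)

    @property
    def difference(self) -> int:
        """Covered significant minus covered non-significant genes."""
        return self.score.tp - self.score.fp


@dataclass
class RulePool:
    """Deduplicated rule entries keyed by (comparison, covered set)."""

    entries: list[PoolEntry] = field(default_factory=list)
    _index: dict = field(default_factory=dict, repr=False)

    def add(
        self,
        rule: Rule,
        score: RuleScore,
        comparison: tuple[str, str],
        config: SearchConfig,
    ) -> None:
        key = (comparison, score.covered)
        entry = self._index.get(key)
        if entry is None:
            entry = PoolEntry(rule=rule, score=score, comparison=comparison)
            self._index[key] = entry
            self.entries.append(entry)
        else:
            # keep the most parsimonious representative
            if (len(rule), rule.term_ids) < (len(entry.rule), entry.rule.term_ids):
                entry.rule = rule
                entry.score = score
        entry.provenance.append(config)

    def __len__(self) -> int:
        return len(self.entries)


def run_grid(
    labelings: Mapping[tuple[str, str], ComparisonLabeling],
    annotations: AnnotationTable,
    graph: OntologyGraph,
    *,
    eval_fns: Sequence[str] = DEFAULT_EVAL_FNS,
    min_levels: Sequence[int] = DEFAULT_MIN_LEVELS,
    max_rules: int = 10,
    max_conjuncts: int = 3,
    beam_width: int = 20,
    seed: int = 0,
) -> RulePool:
    """Induce rules for every (comparison, eval_fn, min_level) combination.

    Individual run failures are logged and skipped so one degenerate setting
    cannot abort the grid.
    """
    pool = RulePool()
    for comparison, labeling in labelings.items():
        for eval_fn in eval_fns:
            for min_level in min_levels:
                config = SearchConfig(
                    eval_fn=eval_fn,
                    min_level=min_level,
                    max_rules=max_rules,
                    max_conjuncts=max_conjuncts,
                    beam_width=beam_width,
                    seed=seed,
                )
                try:
                    found = induce_rules(labeling, annotations, graph, config)
                except ValueError as exc:
                    log.warning(
                        "rule run failed for %s %s minLevel=%d: %s",
                        comparison, eval_fn, min_level, exc,
                    )
                    continue
                for rule, score in found:
                    pool.add(rule, score, comparison, config)
    return pool


@dataclass
class SelectedRule:
    entry: PoolEntry
    t_score: float
    difference: int


def _welch_t(covered_vals: np.ndarray, uncovered_vals: np.ndarray) -> float:
    if len(covered_vals) < 2 or len(uncovered_vals) < 2:
        return float("nan")
    t, _p = stats.ttest_ind(covered_vals, uncovered_vals, equal_var=False)
    return float(t)


def select_rules(
    pool: RulePool,
    expr: ExpressionTable,
    *,
    min_difference: int = 3,
    absolute_difference: bool = False,
) -> list[SelectedRule]:
    """Filter by significant-vs-non-significant difference, rank by t-score.

    difference = tp - fp (``absolute_difference`` switches to |tp - fp|);
    entries below ``min_difference`` are dropped.  The t-score is the Welch
    two-sample t statistic of the per-gene mean expression difference
    (first minus second tissue of the entry's comparison) between covered
    and uncovered genes; entries are sorted by descending |t| then
    difference, with stable order on ties.
    """
    selected: list[SelectedRule] = []
    for entry in pool.entries:
        diff = entry.difference
        if absolute_difference:
            diff = abs(diff)
        if diff < min_difference:
            continue
        t1, t2 = entry.comparison
        per_gene = (
            expr.values[expr.samples_of(t1)].mean(axis=1)
            - expr.values[expr.samples_of(t2)].mean(axis=1)
        )
        covered = per_gene.index.isin(entry.score.covered)
        t_score = _welch_t(per_gene[covered].to_numpy(),
                           per_gene[~covered].to_numpy())
        selected.append(SelectedRule(entry=entry, t_score=t_score,
                                     difference=diff))
    rank = {id(s): i for i, s in enumerate(selected)}
    selected.sort(
        key=lambda s: (
            -abs(s.t_score) if np.isfinite(s.t_score) else float("inf"),
            -s.difference,
            rank[id(s)],
        )
    )
    return selected
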