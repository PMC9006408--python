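"""Per-term enrichment against a significance labeling, coverage
percentages, and exact tests for category tables."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .annotations import AnnotationTable
from .diffexpr import ComparisonLabeling

__all__ = [
    "TermEnrichment",
    "term_enrichment",
    "coverage_percentages",
    "category_fisher",
    "benjamini_hochberg",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermEnrichment:
    """2x2 over-representation summary for one term.

    a = significant & annotated, b = significant & not annotated,
    c = non-significant & annotated, d = non-significant & not annotated.
    """

    term_id: str
    a: int
    b: int
    c: int
    d: int
    p_value: float

    @property
    def annotated(self) -> int:
        return self.a + self.c

    @property
    def universe(self) -> int:
        return self.a + self.b + self.c + self.d


def term_enrichment(
    labeling: ComparisonLabeling, annotations: AnnotationTable
) -> list[TermEnrichment]:
    """One-sided hypergeometric over-representation for every annotated term.

    The tail probability is P(X >= a) for X hypergeometric with the term's
    annotated genes drawn against the significant/non-significant split.
    Terms annotating no universe gene are skipped.  Results are sorted by
    ascending p then term id.
    """
    universe = labeling.universe
    if not annotations.gene_universe >= universe:
        missing = sorted(universe - annotations.gene_universe)[:5]
        raise ValueError(f"labeling genes missing from annotations: {missing}")
    sig = labeling.significant_genes
    n_universe = len(universe)
    n_sig = len(sig)
    out: list[TermEnrichment] = []
    for term_id in sorted(annotations.term_ids):
        annotated = annotations.genes_for_term(term_id) & universe
        if not annotated:
            continue
        a = len(annotated & sig)
        c = len(annotated) - a
        b = n_sig - a
        d = (n_universe - n_sig) - c
        p = float(stats.hypergeom.sf(a - 1, n_universe, a + c, n_sig))
        out.append(TermEnrichment(term_id=term_id, a=a, b=b, c=c, d=d,
                                  p_value=min(p, 1.0)))
    out.sort(key=lambda e: (e.p_value, e.term_id))
    return out


def _round_half_up(value: float, digits: int = 2) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def coverage_percentages(
    upregulated_sets: Mapping[str, Iterable[str]],
    annotations: AnnotationTable,
    term_id: str,
) -> dict[str, float]:
    """Percent of each tissue's upregulated genes annotated to ``term_id``.

    Rounded half-up to two decimals.  An empty upregulated set yields 0.00
    (logged, since the ratio is undefined).
    """
    annotated = annotations.genes_for_term(term_id)
    out: dict[str, float] = {}
    for tissue, genes in upregulated_sets.items():
        genes = frozenset(genes)
        if not genes:
            log.warning("tissue %r has an empty upregulated set", tissue)
            out[tissue] = 0.0
            continue
        pct = 100.0 * len(genes & annotated) / len(genes)
        out[tissue] = _round_half_up(pct)
    return out


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """BH-adjusted p-values, preserving input order."""
    p = np.asarray(list(p_values), dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


# -- exact category tests -----------------------------------------------------

_EXACT_TOTAL_LIMIT = 30
_LOG_TOL = 1e-9


def _log_table_prob(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lg = math.lgamma
    out = sum(lg(r + 1) for r in rows) + sum(lg(c + 1) for c in cols)
    out -= lg(n + 1)
    out -= sum(lg(x + 1) for x in table.ravel())
    return out


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    n_r, n_c = len(rows), len(cols)
    table = np.zeros((n_r, n_c), dtype=int)

    def fill(r: int, c: int, row_left: np.ndarray, col_left: np.ndarray):
        if r == n_r - 1:
            # last row forced by column margins
            if col_left.sum() != row_left[r]:
                return
            table[r, :] = col_left
            yield table.copy()
            return
        if c == n_c - 1:
            v = row_left[r]
            if v > col_left[c]:
                return
            table[r, c] = v
            col_left[c] -= v
            row_left[r] = 0
            yield from fill(r + 1, 0, row_left, col_left)
            row_left[r] = v
            col_left[c] += v
            table[r, c] = 0
            return
        hi = min(row_left[r], col_left[c])
        for v in range(hi + 1):
            table[r, c] = v
            row_left[r] -= v
            col_left[c] -= v
            yield from fill(r, c + 1, row_left, col_left)
            row_left[r] += v
            col_left[c] += v
        table[r, c] = 0

    yield from fill(0, 0, rows.copy(), cols.copy())


def _fisher_exact_rc(table: np.ndarray) -> float:
    obs = _log_table_prob(table)
    p = 0.0
    for cand in _enumerate_tables(table.sum(axis=1), table.sum(axis=0)):
        lp = _log_table_prob(cand)
        if lp <= obs + _LOG_TOL:
            p += math.exp(lp)
    return min(p, 1.0)


def _fisher_mc_rc(table: np.ndarray, draws: int, seed: int | None) -> float:
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    obs = _log_table_prob(table)
    hits = 0
    step = 20_000
    done = 0
    while done < draws:
        m = min(step, draws - done)
        samples = dist.rvs(m, random_state=rng)
        for s in np.atleast_3d(samples).reshape(m, *table.shape):
            if _log_table_prob(s.astype(int)) <= obs + _LOG_TOL:
                hits += 1
        done += m
    return (hits + 1) / (draws + 1)


def category_fisher(
    contingency,
    *,
    seed: int | None = None,
    mc_draws: int = 100_000,
) -> float:
    """Two-sided Fisher exact p for an r x c count table.

    2x2 tables use the standard exact test.  Larger tables are evaluated by
    full enumeration over fixed-margin tables when the total count is <= 30,
    and by a seeded Monte-Carlo tail estimate (Patefield sampling) otherwise.
    All-zero rows or columns are dropped with a warning.
    """
    table = np.asarray(contingency, dtype=int)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        log.warning("dropping zero-margin rows/columns from contingency table")
        table = table[keep_rows][:, keep_cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if table.sum() <= _EXACT_TOTAL_LIMIT:
        return _fisher_exact_rc(table)
    return _fisher_mc_rc(table, mc_draws, seed)
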