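"""qPCR differential expression: imputation, reference normalization,
one-way ANOVA with Tukey HSD post-hoc, pairwise significance labelings,
per-tissue upregulated counts and the two-group separation filter.

Conventions
-----------
Cq is the quantification cycle (higher = less transcript).  Expression is
reported as ``-dCq = -(Cq_gene - Cq_reference)`` which equals log2 relative
quantity under the usual perfect-efficiency assumption, so a +1 change is a
doubling and the separation filter's delta threshold applies directly on this
scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._sr import studentized_range_sf

__all__ = [
    "CqMatrix",
    "ExpressionTable",
    "ComparisonLabeling",
    "DiffExprStats",
    "impute_missing",
    "normalize",
    "anova_tukey",
    "label_groups",
    "count_upregulated",
    "dss_separation_filter",
]

log = logging.getLogger(__name__)

IMPUTE_OFFSET = 2.0  #: added to the per-gene max Cq when filling missing wells
CQ_MAX = 45.0


@dataclass
class CqMatrix:
    """Raw Cq values, genes x samples; NaN marks missing wells."""

    values: pd.DataFrame
    sample_tissue: Mapping[str, str]
    reference_gene: str = "HSP90"
    imputed: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = self.values.astype(float)
        missing_samples = [
            s for s in self.values.columns if s not in self.sample_tissue
        ]
        if missing_samples:
            raise ValueError(f"samples without tissue label: {missing_samples}")
        tissues = {self.sample_tissue[s] for s in self.values.columns}
        if len(tissues) < 2:
            raise ValueError("need at least two tissues")
        if self.reference_gene not in self.values.index:
            raise ValueError(f"reference gene {self.reference_gene!r} not in matrix")
        ref = self.values.loc[self.reference_gene]
        if ref.isna().any():
            raise ValueError("reference gene has missing values")
        observed = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = np.nansum((observed <= 0) | (observed > CQ_MAX))
        if bad:
            raise ValueError(f"{int(bad)} Cq values outside (0, {CQ_MAX}]")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted({self.sample_tissue[s] for s in self.values.columns}))

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_tissue[s] == tissue]


@dataclass
class ExpressionTable:
    """Normalized log-scale expression; reference gene removed, no NaNs."""

    values: pd.DataFrame
    sample_tissue: Mapping[str, str]
    imputed: pd.DataFrame

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing values")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted({self.sample_tissue[s] for s in self.values.columns}))

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_tissue[s] == tissue]

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class ComparisonLabeling:
    """Per-gene significance and direction for one ordered tissue pair.

    ``direction[g]`` is the tissue the gene is up in, or ``None``.
    """

    comparison: tuple[str, str]
    significant: pd.Series
    direction: pd.Series
    p_value: pd.Series

    def __post_init__(self):
        mismatch = (self.direction.notna()) != self.significant.astype(bool)
        if mismatch.any():
            bad = list(self.significant.index[mismatch])[:5]
            raise ValueError(f"direction/significance mismatch for genes {bad}")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.significant.index)

    @property
    def significant_genes(self) -> frozenset[str]:
        return frozenset(self.significant.index[self.significant])

    @property
    def nonsignificant_genes(self) -> frozenset[str]:
        return frozenset(self.significant.index[~self.significant])

    def upregulated_in(self, tissue: str) -> frozenset[str]:
        return frozenset(self.direction.index[self.direction == tissue])


@dataclass
class DiffExprStats:
    """Output bundle of :func:`anova_tukey`."""

    anova: pd.DataFrame  # columns: F, p, degenerate
    pairwise: dict[tuple[str, str], pd.DataFrame]  # columns: mean_diff, p_adj
    tissues: tuple[str, ...]


def impute_missing(cq: CqMatrix) -> CqMatrix:
    """Fill missing wells with the per-gene max observed Cq + 2.

    Genes with no observed value at all are dropped with a warning.  The
    reference gene is never missing (enforced at construction).
    """
    values = cq.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        dropped = list(values.index[all_missing])
        log.warning("dropping %d genes with no observed Cq: %s",
                    len(dropped), dropped[:5])
        values = values.loc[~all_missing]
    imputed_mask = values.isna()
    fill = values.max(axis=1) + IMPUTE_OFFSET
    values = values.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return CqMatrix(
        values=values,
        sample_tissue=cq.sample_tissue,
        reference_gene=cq.reference_gene,
        imputed=imputed_mask,
    )


def normalize(cq: CqMatrix, *, log_base: float = 2.0) -> ExpressionTable:
    """Reference-normalize: expression = -(Cq - Cq_ref) per sample.

    On base 2 this is log2 relative quantity.  ``log_base`` rescales to other
    logarithms (values multiplied by log(2)/log(base)).
    """
    if cq.values.isna().any().any():
        raise ValueError("impute_missing must be applied before normalize")
    ref = cq.values.loc[cq.reference_gene]
    expr = -(cq.values.drop(index=cq.reference_gene) - ref)
    if log_base != 2.0:
        expr = expr * (math.log(2.0) / math.log(log_base))
    imputed = cq.imputed
    if imputed is None:
        imputed = pd.DataFrame(False, index=expr.index, columns=expr.columns)
    else:
        imputed = imputed.reindex(index=expr.index, columns=expr.columns,
                                  fill_value=False)
    return ExpressionTable(values=expr, sample_tissue=dict(cq.sample_tissue),
                           imputed=imputed)


def _ordered_pairs(tissues: Iterable[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(tissues), 2))


def anova_tukey(expr: ExpressionTable) -> DiffExprStats:
    """Per-gene one-way ANOVA across tissues plus Tukey HSD pairwise tests.

    Pairwise adjusted p-values use the studentized range distribution with
    the Tukey-Kramer standard error, evaluated with the vectorized
    quadrature in :mod:`semclust._sr`.  Genes where the pooled within-group
    variance is exactly zero are flagged ``degenerate`` and get p = 0 for
    pairs with unequal means (p = 1 otherwise).
    """
    tissues = expr.tissues
    groups = {t: expr.values[expr.samples_of(t)].to_numpy() for t in tissues}
    for t, arr in groups.items():
        if arr.shape[1] < 2:
            raise ValueError(f"tissue {t!r} has fewer than 2 replicates")
    k = len(tissues)
    n_total = sum(arr.shape[1] for arr in groups.values())
    df_within = n_total - k

    means = {t: arr.mean(axis=1) for t, arr in groups.items()}
    ss_within = sum(
        ((arr - means[t][:, None]) ** 2).sum(axis=1) for t, arr in groups.items()
    )
    grand = sum(arr.sum(axis=1) for arr in groups.values()) / n_total
    ss_between = sum(
        arr.shape[1] * (means[t] - grand) ** 2 for t, arr in groups.items()
    )
    mse = ss_within / df_within
    degenerate = mse == 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / (k - 1)) / mse
    anova_p = np.where(
        degenerate,
        np.where(ss_between > 0, 0.0, 1.0),
        stats.f.sf(f_stat, k - 1, df_within),
    )
    anova = pd.DataFrame(
        {"F": f_stat, "p": anova_p, "degenerate": degenerate},
        index=expr.genes,
    )

    pairwise: dict[tuple[str, str], pd.DataFrame] = {}
    pairs = _ordered_pairs(tissues)
    # batch all q statistics into one sf call per (k, df)
    q_all = []
    diffs = {}
    for t1, t2 in pairs:
        n1, n2 = groups[t1].shape[1], groups[t2].shape[1]
        diff = means[t1] - means[t2]
        se = np.sqrt(mse * 0.5 * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(diff) / se
        diffs[(t1, t2)] = diff
        q_all.append(q)
    q_flat = np.concatenate(q_all)
    finite = np.isfinite(q_flat)
    p_flat = np.ones_like(q_flat)
    if finite.any():
        p_flat[finite] = studentized_range_sf(q_flat[finite], k, df_within)
    n_genes = len(expr.genes)
    for i, (t1, t2) in enumerate(pairs):
        p_adj = p_flat[i * n_genes : (i + 1) * n_genes].copy()
        diff = diffs[(t1, t2)]
        p_adj = np.where(degenerate, np.where(diff != 0, 0.0, 1.0), p_adj)
        pairwise[(t1, t2)] = pd.DataFrame(
            {"mean_diff": diff, "p_adj": p_adj}, index=expr.genes
        )
    return DiffExprStats(anova=anova, pairwise=pairwise, tissues=tissues)


def label_groups(
    stats_out: DiffExprStats, alpha: float = 0.01
) -> dict[tuple[str, str], ComparisonLabeling]:
    """Turn Tukey pairwise p-values into significance labelings.

    Strict inequality: a gene is significant iff adjusted p < alpha.
    Direction is the tissue with the higher mean expression.
    """
    out: dict[tuple[str, str], ComparisonLabeling] = {}
    for (t1, t2), table in stats_out.pairwise.items():
        sig = table["p_adj"] < alpha
        direction = pd.Series(None, index=table.index, dtype=object)
        direction[sig & (table["mean_diff"] > 0)] = t1
        direction[sig & (table["mean_diff"] < 0)] = t2
        direction = direction.where(direction.notna(), None)
        # a zero mean difference cannot be called in either direction
        sig = sig & (table["mean_diff"] != 0)
        out[(t1, t2)] = ComparisonLabeling(
            comparison=(t1, t2),
            significant=sig,
            direction=direction,
            p_value=table["p_adj"].copy(),
        )
    return out


def count_upregulated(
    labelings: Mapping[tuple[str, str], ComparisonLabeling],
    *,
    distinct: bool = True,
) -> dict[str, int]:
    """Per-tissue count of genes up in that tissue in >= 1 of its comparisons.

    ``distinct=True`` (default) counts the union of genes; ``False`` sums the
    per-comparison lists, counting a gene once per comparison it is up in.
    """
    sets: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for labeling in labelings.values():
        for tissue in labeling.comparison:
            up = labeling.upregulated_in(tissue)
            sets.setdefault(tissue, set()).update(up)
            totals[tissue] = totals.get(tissue, 0) + len(up)
    if distinct:
        return {t: len(g) for t, g in sets.items()}
    return totals


def upregulated_sets(
    labelings: Mapping[tuple[str, str], ComparisonLabeling]
) -> dict[str, frozenset[str]]:
    """Union-of-comparisons upregulated gene set per tissue."""
    sets: dict[str, set[str]] = {}
    for labeling in labelings.values():
        for tissue in labeling.comparison:
            sets.setdefault(tissue, set()).update(labeling.upregulated_in(tissue))
    return {t: frozenset(g) for t, g in sets.items()}


def dss_separation_filter(
    treated: ExpressionTable,
    control: ExpressionTable,
    delta: float = 1.25,
) -> dict[str, str]:
    """Two-group selection without a hypothesis test (small-n design).

    A gene is selected iff |mean(treated) - mean(control)| > ``delta``
    (strict) AND the two value ranges are completely separated (the minimum
    of the higher group strictly exceeds the maximum of the lower group).
    Returns ``{gene: "up" | "down"}`` where "up" means higher expression in
    the treated group.
    """
    common = treated.values.index.intersection(control.values.index)
    if len(common) == 0:
        raise ValueError("no shared genes between the two tables")
    out: dict[str, str] = {}
    tv = treated.values.loc[common]
    cv = control.values.loc[common]
    mean_diff = tv.mean(axis=1) - cv.mean(axis=1)
    t_min, t_max = tv.min(axis=1), tv.max(axis=1)
    c_min, c_max = cv.min(axis=1), cv.max(axis=1)
    up_sep = t_min > c_max
    down_sep = c_min > t_max
    selected_up = (mean_diff > delta) & up_sep
    selected_down = (-mean_diff > delta) & down_sep
    for gene in common:
        if selected_up[gene]:
            out[gene] = "up"
        elif selected_down[gene]:
            out[gene] = "down"
    return out
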