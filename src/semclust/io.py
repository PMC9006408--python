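"""Tabular readers/writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .diffexpr import ComparisonLabeling, CqMatrix, DiffExprStats

__all__ = [
    "read_cq_tsv",
    "read_sample_sheet",
    "load_cq_matrix",
    "write_stats",
    "write_labelings",
]


def read_cq_tsv(path: str | Path) -> pd.DataFrame:
    """Cq matrix TSV: first column gene_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    return df.astype(float)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Sample sheet TSV with sample_id and tissue columns."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "tissue" not in cols:
        raise ValueError(
            f"{path}: sample sheet needs 'sample_id' and 'tissue' columns, "
            f"got {list(df.columns)}"
        )
    return dict(zip(df[cols["sample_id"]].astype(str),
                    df[cols["tissue"]].astype(str)))


def load_cq_matrix(
    cq_path: str | Path,
    samples_path: str | Path,
    reference_gene: str = "HSP90",
) -> CqMatrix:
    values = read_cq_tsv(cq_path)
    sample_tissue = read_sample_sheet(samples_path)
    known = [s for s in values.columns if s in sample_tissue]
    if len(known) < len(values.columns):
        unknown = [s for s in values.columns if s not in sample_tissue]
        raise ValueError(f"samples missing from sheet: {unknown}")
    return CqMatrix(values=values, sample_tissue=sample_tissue,
                    reference_gene=reference_gene)


def write_stats(stats: DiffExprStats, path: str | Path) -> None:
    """Per-gene ANOVA and pairwise Tukey results as one wide TSV."""
    out = stats.anova.copy()
    out.columns = [f"anova_{c}" for c in out.columns]
    for (t1, t2), table in stats.pairwise.items():
        tag = f"{t1}_vs_{t2}"
        out[f"{tag}_mean_diff"] = table["mean_diff"]
        out[f"{tag}_p_adj"] = table["p_adj"]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_labelings(
    labelings: Mapping[tuple[str, str], ComparisonLabeling], path: str | Path
) -> None:
    rows = []
    for (t1, t2), lab in labelings.items():
        for gene in lab.significant.index:
            rows.append(
                {
                    "gene_id": gene,
                    "comparison": f"{t1}_vs_{t2}",
                    "significant": bool(lab.significant[gene]),
                    "direction": lab.direction[gene] or "none",
                    "p_adj": lab.p_value[gene],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
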