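"""End-to-end orchestration: diffexpr -> enrichment -> rule grid -> selection.

Every report carries the configuration hash so reruns are verifiable; all
randomness flows through the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotations import load_annotations
from .diffexpr import (
    anova_tukey,
    count_upregulated,
    impute_missing,
    label_groups,
    normalize,
    upregulated_sets,
)
from .enrichment import benjamini_hochberg, coverage_percentages, term_enrichment
from .io import load_cq_matrix, write_labelings, write_stats
from .ontology import load_obo, merge
from .selection import run_grid, select_rules

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cq_path: str
    samples_path: str
    obo_paths: Sequence[str]
    annotations_path: str
    output_dir: str
    reference_gene: str = "HSP90"
    alpha: float = 0.01
    dss_delta: float = 1.25
    eval_fns: Sequence[str] = ("ACC", "AUC", "F1")
    min_levels: Sequence[int] = (0, 2, 3, 4, 5, 6)
    max_rules: int = 10
    max_conjuncts: int = 3
    beam_width: int = 20
    min_difference: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["obo_paths"] = list(self.obo_paths)
        d["eval_fns"] = list(self.eval_fns)
        d["min_levels"] = list(self.min_levels)
        return d

    def config_hash(self) -> str:
        # output_dir does not influence any computed result
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all stages and write the report bundle; returns output paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    for p in [config.cq_path, config.samples_path, config.annotations_path,
              *config.obo_paths]:
        if not Path(p).exists():
            raise FileNotFoundError(f"pipeline input does not exist: {p}")

    cq = load_cq_matrix(config.cq_path, config.samples_path,
                        config.reference_gene)
    cq = impute_missing(cq)
    expr = normalize(cq)
    stats = anova_tukey(expr)
    labelings = label_groups(stats, alpha=config.alpha)
    up_sets = upregulated_sets(labelings)
    counts = count_upregulated(labelings)

    graph = merge(*(load_obo(p) for p in config.obo_paths))
    universe = frozenset(expr.genes)
    annotations = load_annotations(config.annotations_path, graph, universe)

    paths: dict[str, str] = {}

    stats_path = outdir / "gene_stats.tsv"
    write_stats(stats, stats_path)
    paths["stats"] = str(stats_path)

    labeling_path = outdir / "labelings.tsv"
    write_labelings(labelings, labeling_path)
    paths["labelings"] = str(labeling_path)

    enrich_rows = []
    for comparison, labeling in labelings.items():
        results = term_enrichment(labeling, annotations)
        adj = benjamini_hochberg([e.p_value for e in results])
        for e, q in zip(results, adj):
            cov = coverage_percentages(up_sets, annotations, e.term_id)
            row = {
                "comparison": f"{comparison[0]}_vs_{comparison[1]}",
                "term_id": e.term_id,
                "name": graph[e.term_id].name if e.term_id in graph else "",
                "a": e.a, "b": e.b, "c": e.c, "d": e.d,
                "p": e.p_value,
                "p_bh": q,
            }
            for tissue, pct in sorted(cov.items()):
                row[f"pct_{tissue}_up"] = pct
            enrich_rows.append(row)
    enrich_path = outdir / "enrichment.tsv"
    pd.DataFrame(enrich_rows).to_csv(enrich_path, sep="\t", index=False)
    paths["enrichment"] = str(enrich_path)

    pool = run_grid(
        labelings, annotations, graph,
        eval_fns=config.eval_fns,
        min_levels=config.min_levels,
        max_rules=config.max_rules,
        max_conjuncts=config.max_conjuncts,
        beam_width=config.beam_width,
        seed=config.seed,
    )
    rule_rows = []
    for entry in pool.entries:
        rule_rows.append(
            {
                "comparison": f"{entry.comparison[0]}_vs_{entry.comparison[1]}",
                "terms": "|".join(entry.rule.term_ids),
                "names": "|".join(
                    graph[t].name for t in entry.rule.term_ids if t in graph
                ),
                "tp": entry.score.tp, "fp": entry.score.fp,
                "tn": entry.score.tn, "fn": entry.score.fn,
                "acc": entry.score.acc, "auc": entry.score.auc,
                "f1": entry.score.f1,
                "covered": "|".join(sorted(entry.score.covered)),
                "n_runs": len(entry.provenance),
            }
        )
    rules_path = outdir / "rules.tsv"
    pd.DataFrame(rule_rows).to_csv(rules_path, sep="\t", index=False)
    paths["rules"] = str(rules_path)

    selected = select_rules(pool, expr, min_difference=config.min_difference)
    sel_rows = []
    for s in selected:
        sel_rows.append(
            {
                "comparison": f"{s.entry.comparison[0]}_vs_{s.entry.comparison[1]}",
                "terms": "|".join(s.entry.rule.term_ids),
                "t_score": s.t_score,
                "difference": s.difference,
                "tp": s.entry.score.tp,
                "fp": s.entry.score.fp,
                "f1": s.entry.score.f1,
                "covered": "|".join(sorted(s.entry.score.covered)),
            }
        )
    sel_path = outdir / "selection.tsv"
    pd.DataFrame(sel_rows).to_csv(sel_path, sep="\t", index=False)
    paths["selection"] = str(sel_path)

    sel_json = outdir / "selection.json"
    sel_json.write_text(json.dumps(sel_rows, indent=2))
    paths["selection_json"] = str(sel_json)

    run_log = {
        "semclust_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "upregulated_counts": counts,
        "n_pool_rules": len(pool),
        "n_selected": len(selected),
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True))
    paths["run_log"] = str(log_path)
    return paths
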