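"""Synthetic scenario generation: random layered ontology DAGs, sparse
annotations with a planted conjunctive rule, and Cq matrices with planted
tissue effects, replicate noise and expression-biased dropout.

Everything is deterministic given (parameters, seed) so the whole pipeline
can be tested against known ground truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationTable, propagate_true_path, genes_with_all_terms
from .diffexpr import ComparisonLabeling, CqMatrix
from .ontology import OntologyGraph, OntologyTerm, write_obo
from .rules import Rule

__all__ = [
    "SyntheticScenario",
    "make_ontology",
    "plant_rule_scenario",
    "simulate_cq",
    "make_scenario",
    "write_scenario",
]

DEFAULT_TISSUES = ("colon", "small_intestine", "stomach")
REFERENCE_GENE = "HSP90"


def make_ontology(
    n_terms: int, depth: int, branching: int = 2, seed: int = 0
) -> OntologyGraph:
    """Random layered DAG with ``depth + 1`` layers.

    Layer 0 holds the roots; each non-root term draws 1-2 parents from the
    layer directly above, so a term's shortest-path level equals its layer
    and the maximum level is exactly ``depth`` (the deepest layer is always
    populated).
    """
    if depth < 0 or branching < 1:
        raise ValueError("depth >= 0 and branching >= 1 required")
    if n_terms < depth + 1:
        raise ValueError(
            f"infeasible: {n_terms} terms cannot span depth {depth}"
        )
    rng = np.random.default_rng(seed)
    sizes = [1] * (depth + 1)
    remaining = n_terms - (depth + 1)
    while remaining > 0:
        placed = False
        for layer in range(1, depth + 1):
            if sizes[layer] < sizes[layer - 1] * branching:
                sizes[layer] += 1
                remaining -= 1
                placed = True
                if remaining == 0:
                    break
        if not placed:  # capacity exhausted; widen the deepest layer
            sizes[-1] += remaining
            remaining = 0

    terms: dict[str, OntologyTerm] = {}
    layers: list[list[str]] = []
    counter = 0
    for layer, size in enumerate(sizes):
        ids: list[str] = []
        for _ in range(size):
            tid = f"SYN:{counter:07d}"
            counter += 1
            if layer == 0:
                parents: tuple[str, ...] = ()
            else:
                n_parents = int(rng.integers(1, min(2, len(layers[-1])) + 1))
                picks = rng.choice(len(layers[-1]), size=n_parents,
                                   replace=False)
                parents = tuple(layers[-1][i] for i in sorted(picks))
            terms[tid] = OntologyTerm(
                term_id=tid,
                name=f"synthetic term {counter - 1}",
                namespace="synthetic",
                parent_ids=parents,
            )
            ids.append(tid)
        layers.append(ids)
    return OntologyGraph(terms)


def _pick_non_ancestral(
    graph: OntologyGraph, rule_length: int, min_level: int, rng
) -> tuple[str, ...]:
    eligible = sorted(
        t for t in graph if graph.term_level(t) >= min_level
    )
    if len(eligible) < rule_length:
        raise ValueError(
            f"need {rule_length} terms at level >= {min_level}, "
            f"found {len(eligible)}"
        )
    for _ in range(200):
        picks = rng.choice(len(eligible), size=rule_length, replace=False)
        chosen = [eligible[i] for i in picks]
        ok = all(
            not ((graph.ancestors(a) - {a}) & set(chosen))
            for a in chosen
        )
        if ok:
            return tuple(sorted(chosen))
    raise ValueError("could not find mutually non-ancestral terms")


def plant_rule_scenario(
    graph: OntologyGraph,
    n_genes: int,
    rule_length: int = 2,
    base_density: float = 0.05,
    noise: float = 0.0,
    seed: int = 0,
    *,
    target_fraction: float = 0.3,
    min_term_level: int = 2,
) -> tuple[AnnotationTable, ComparisonLabeling, Rule]:
    """Plant a conjunctive rule and derive a noisy significance labeling.

    A random gene subset is annotated to every rule term; background
    annotations are sprinkled at ``base_density``.  The clean significant
    set is the rule's post-closure coverage, then each gene's label is
    flipped independently with probability ``noise`` (must be < 0.5).
    With ``noise=0`` the planted rule separates the classes perfectly.
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    rule_terms = _pick_non_ancestral(graph, rule_length, min_term_level, rng)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    n_target = max(1, round(target_fraction * n_genes))
    target_idx = rng.choice(n_genes, size=n_target, replace=False)
    targets = {genes[i] for i in target_idx}

    pairs: set[tuple[str, str]] = set()
    for g in targets:
        for t in rule_terms:
            pairs.add((g, t))
    all_terms = sorted(graph)
    background = rng.random((n_genes, len(all_terms))) < base_density
    for gi, g in enumerate(genes):
        for ti in np.nonzero(background[gi])[0]:
            pairs.add((g, all_terms[ti]))

    table = AnnotationTable(
        pairs=frozenset(pairs), gene_universe=frozenset(genes)
    )
    table = propagate_true_path(table, graph)

    covered = genes_with_all_terms(table, rule_terms)
    flips = rng.random(n_genes) < noise
    significant = pd.Series(
        [(g in covered) != bool(flips[i]) for i, g in enumerate(genes)],
        index=genes,
    )
    direction = pd.Series(None, index=genes, dtype=object)
    direction[significant] = "case"
    p_value = pd.Series(np.where(significant, 0.0, 1.0), index=genes)
    labeling = ComparisonLabeling(
        comparison=("case", "control"),
        significant=significant,
        direction=direction,
        p_value=p_value,
    )
    return table, labeling, Rule(rule_terms)


def simulate_cq(
    n_genes: int,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    replicates: int = 3,
    effect_map: Mapping[str, Mapping[str, float]] | None = None,
    sigma: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> CqMatrix:
    """Simulate a Cq matrix with planted per-tissue expression effects.

    ``effect_map[gene][tissue]`` raises expression (lowers Cq) of that gene
    in that tissue.  The reference gene is appended, held at Cq 20 with
    tiny jitter and never missing.  Dropout is right-censoring-like: cells
    with higher Cq (weaker expression) are more likely to go missing, and
    every gene keeps at least one observed well.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= missing_rate < 0.3:
        raise ValueError("missing_rate must be in [0, 0.3)")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(replicates)]
    sample_tissue = {f"{t}_{r + 1}": t for t in tissues for r in range(replicates)}

    baseline = rng.uniform(24.0, 32.0, size=n_genes)
    effect = np.zeros((n_genes, len(samples)))
    if effect_map:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for g, per_tissue in effect_map.items():
            if g not in gene_pos:
                raise KeyError(f"effect_map gene {g!r} not simulated")
            for si, s in enumerate(samples):
                effect[gene_pos[g], si] = per_tissue.get(sample_tissue[s], 0.0)
    cq = baseline[:, None] - effect + rng.normal(0.0, sigma, effect.shape)
    cq = np.clip(cq, 1.0, 45.0)
    values = pd.DataFrame(cq, index=genes, columns=samples)

    if missing_rate > 0:
        flat = values.to_numpy().ravel()
        n_cells = flat.size
        n_missing = rng.binomial(n_cells, missing_rate)
        if n_missing:
            # dropout probability increases with Cq (weak expression)
            w = flat - flat.min() + 0.25 * (flat.max() - flat.min() + 1e-9)
            w = w / w.sum()
            picks = rng.choice(n_cells, size=n_missing, replace=False, p=w)
            mask = np.zeros(n_cells, dtype=bool)
            mask[picks] = True
            mask = mask.reshape(values.shape)
            # never blank out an entire gene row
            for gi in range(n_genes):
                if mask[gi].all():
                    keep = rng.integers(0, mask.shape[1])
                    mask[gi, keep] = False
            arr = values.to_numpy()
            arr[mask] = np.nan
            values = pd.DataFrame(arr, index=genes, columns=samples)

    ref = 20.0 + rng.normal(0.0, 0.05, size=len(samples))
    values.loc[REFERENCE_GENE] = ref
    return CqMatrix(values=values, sample_tissue=sample_tissue,
                    reference_gene=REFERENCE_GENE)


@dataclass
class SyntheticScenario:
    """Bundle of all generated artifacts plus the planted truth."""

    graph: OntologyGraph
    annotations: AnnotationTable
    labeling: ComparisonLabeling
    planted_rule: Rule
    cq: CqMatrix
    effect_map: dict
    seed: int


def make_scenario(
    n_genes: int = 370,
    n_terms: int = 120,
    depth: int = 5,
    rule_length: int = 2,
    base_density: float = 0.03,
    noise: float = 0.0,
    effect_size: float = 3.0,
    sigma: float = 0.5,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> SyntheticScenario:
    """Full scenario: ontology + planted rule + Cq matrix.

    Genes labeled significant by the planted rule receive an expression
    boost of ``effect_size`` (in sigma units, on the Cq scale) in the first
    tissue, so the planted semantics propagate into the simulated
    measurements.
    """
    graph = make_ontology(n_terms, depth, seed=seed)
    table, labeling, rule = plant_rule_scenario(
        graph, n_genes, rule_length, base_density, noise, seed=seed + 1
    )
    boost = effect_size * sigma
    effect_map = {
        g: {DEFAULT_TISSUES[0]: boost}
        for g in labeling.significant_genes
    }
    cq = simulate_cq(
        n_genes,
        effect_map=effect_map,
        sigma=sigma,
        missing_rate=missing_rate,
        seed=seed + 2,
    )
    return SyntheticScenario(
        graph=graph,
        annotations=table,
        labeling=labeling,
        planted_rule=rule,
        cq=cq,
        effect_map=effect_map,
        seed=seed,
    )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict:
    """Write OBO, annotation TSV, Cq TSV, sample sheet and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "cq": outdir / "cq.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_obo(scenario.graph, paths["obo"])
    from .annotations import write_annotations

    write_annotations(scenario.annotations, paths["annotations"])
    cq = scenario.cq.values.copy()
    cq.index.name = "gene_id"
    cq.to_csv(paths["cq"], sep="\t", na_rep="")
    sheet = pd.DataFrame(
        {
            "sample_id": list(scenario.cq.values.columns),
            "tissue": [
                scenario.cq.sample_tissue[s] for s in scenario.cq.values.columns
            ],
        }
    )
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    truth = {
        "seed": scenario.seed,
        "planted_rule": list(scenario.planted_rule.term_ids),
        "significant_genes": sorted(scenario.labeling.significant_genes),
        "effect_map": scenario.effect_map,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
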