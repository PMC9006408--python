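# semclust

Semantic clustering of qPCR expression profiles. Starting from a raw
gene × sample Cq matrix with tissue labels, one or more OBO ontologies and a
gene→term annotation table, `semclust`:

1. imputes missing Cq wells (per-gene max + 2), normalizes to a reference
   gene (expression = −ΔCq, i.e. log2 relative quantity);
2. labels every gene significant/non-significant per pairwise tissue
   comparison via one-way ANOVA with Tukey HSD post-hoc (fast vectorized
   studentized-range quadrature), with per-tissue upregulated counts and a
   small-n two-group separation filter (|Δmean| > 1.25 ΔCq and completely
   separated ranges);
3. scores every ontology term against each labeling (one-sided
   hypergeometric over-representation), computes per-tissue coverage
   percentages and exact Fisher tests for category tables;
4. induces conjunctive ontology-term rules ("semantic biclusters") that
   discriminate significant from non-significant genes with a deterministic
   beam search under ACC/AUC/F1 evaluation and minimum-term-level
   constraints, pools them across a parameter grid and ranks the pool by a
   Welch t-score with a minimum significant-vs-non-significant difference;
5. ships a synthetic-data generator (random ontology DAGs, planted
   conjunctive rules, planted tissue effects, expression-biased dropout) so
   every stage is testable against ground truth.

Annotations are closed under the true-path rule at load time: a gene
annotated to a term is annotated to all of the term's ancestors.

## CLI

```bash
# generate a synthetic scenario (OBO + annotations + Cq + sample sheet + truth)
semclust simulate --out scenario/ --seed 1 --genes 370 --terms 120 --depth 5

# ontology summary
semclust ontology stats scenario/ontology.obo

# differential expression + labelings
semclust diffexpr --cq scenario/cq.tsv --samples scenario/samples.tsv --out reports/

# enrichment table
semclust enrich --cq scenario/cq.tsv --samples scenario/samples.tsv \
    --obo scenario/ontology.obo --annotations scenario/annotations.tsv \
    --out reports/enrichment.tsv

# rule induction for one setting
semclust rules --cq scenario/cq.tsv --samples scenario/samples.tsv \
    --obo scenario/ontology.obo --annotations scenario/annotations.tsv \
    --eval-fn F1 --min-level 2 --out reports/rules.tsv

# two-group separation filter (treated vs control)
semclust dss-filter --treated-cq t.tsv --treated-samples ts.tsv \
    --control-cq c.tsv --control-samples cs.tsv

# full pipeline from a YAML config (all thresholds overridable by flags)
semclust run --config config.yaml --alpha 0.01 --seed 1
```

A minimal `config.yaml`:

```yaml
cq_path: scenario/cq.tsv
samples_path: scenario/samples.tsv
obo_paths: [scenario/ontology.obo]
annotations_path: scenario/annotations.tsv
output_dir: reports
alpha: 0.01
min_levels: [0, 2, 3, 4, 5, 6]
eval_fns: [ACC, AUC, F1]
max_rules: 10
min_difference: 3
seed: 1
```

`run` writes `gene_stats.tsv`, `labelings.tsv`, `enrichment.tsv`,
`rules.tsv`, `selection.tsv`/`.json` and a `run_log.json` carrying the
package version, the full config and its hash; reruns of the same config
produce identical reports.

## Layout

```
src/semclust/
  ontology.py     OBO parsing, DAG queries, term levels
  annotations.py  gene–term tables, true-path closure, conjunction coverage
  diffexpr.py     imputation, ΔCq normalization, ANOVA + Tukey, labelings
  _sr.py          vectorized studentized-range tail probabilities
  enrichment.py   hypergeometric term enrichment, coverage %, Fisher tests
  rules.py        conjunctive rule language + beam-search induction
  selection.py    grid pooling, dedup, t-score ranking
  synthetic.py    scenario generators with planted ground truth
  pipeline.py     end-to-end orchestration + run log
  cli.py          click command group
tests/            pytest suite; oracles.py holds independent references
```
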