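import textwrap

import numpy as np
import pandas as pd
import pytest

from semclust.annotations import AnnotationTable, propagate_true_path
from semclust.diffexpr import ComparisonLabeling, CqMatrix
from semclust.ontology import OntologyGraph, OntologyTerm

CHAIN_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    default-namespace: toy

    [Term]
    id: T:R
    name: root

    [Term]
    id: T:A
    name: mid
    is_a: T:R

    [Term]
    id: T:B
    name: leaf
    is_a: T:A
    """
)


def graph_from_parents(parents: dict[str, list[str]]) -> OntologyGraph:
    return OntologyGraph(
        {
            tid: OntologyTerm(
                term_id=tid, name=tid, namespace="toy",
                parent_ids=tuple(ps),
            )
            for tid, ps in parents.items()
        }
    )


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return path


@pytest.fixture
def chain_graph():
    return graph_from_parents({"T:R": [], "T:A": ["T:R"], "T:B": ["T:A"]})


@pytest.fixture
def diamond_graph():
    # R -> {A, B} -> C
    return graph_from_parents(
        {"T:R": [], "T:A": ["T:R"], "T:B": ["T:R"], "T:C": ["T:A", "T:B"]}
    )


def make_labeling(universe, significant, comparison=("case", "control")):
    universe = sorted(universe)
    sig = pd.Series([g in significant for g in universe], index=universe)
    direction = pd.Series(None, index=universe, dtype=object)
    direction[sig] = comparison[0]
    p = pd.Series(np.where(sig, 0.001, 0.9), index=universe)
    return ComparisonLabeling(
        comparison=comparison, significant=sig, direction=direction, p_value=p
    )


def make_table(pairs, universe, graph=None, close=True):
    table = AnnotationTable(
        pairs=frozenset(pairs), gene_universe=frozenset(universe)
    )
    if close:
        assert graph is not None
        table = propagate_true_path(table, graph)
    return table


@pytest.fixture
def toy_cq():
    """4 genes + reference, 3 tissues x 2 samples, one missing well."""
    samples = ["colon_1", "colon_2", "si_1", "si_2", "sto_1", "sto_2"]
    values = pd.DataFrame(
        {
            "colon_1": [24.0, 30.0, 28.0, np.nan, 20.0],
            "colon_2": [24.5, 30.5, 28.2, 27.0, 20.0],
            "si_1": [26.0, 25.0, 28.1, 27.2, 20.0],
            "si_2": [26.5, 25.5, 28.3, 27.1, 20.0],
            "sto_1": [25.0, 27.0, 28.0, 27.3, 20.0],
            "sto_2": [25.2, 27.2, 28.2, 27.2, 20.0],
        },
        index=["g1", "g2", "g3", "g4", "HSP90"],
    )
    tissue = {s: s.rsplit("_", 1)[0] for s in samples}
    return CqMatrix(values=values, sample_tissue=tissue, reference_gene="HSP90")
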