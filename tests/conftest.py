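import numpy as np
import pytest

from kgrn.knowledge_graph import KnowledgeGraph, Triple, partition_entities
from kgrn.synthetic import SyntheticScenario, simulate_grn, simulate_kg


def kg_from_triples(triples, expression_genes=None):
    """Build a (optionally partitioned) KnowledgeGraph from raw tuples."""
    ts = {Triple(h, r, t) for h, r, t in triples}
    kg = KnowledgeGraph(
        entities={t.head for t in ts} | {t.tail for t in ts}, triples=ts
    )
    if expression_genes is not None:
        kg = partition_entities(kg, expression_genes)
    return kg


@pytest.fixture
def small_scenario():
    return SyntheticScenario(n_tfs=5, n_targets=25, n_cells=40, seed=7,
                             kg_n_triples=40, kg_extra_entities=6)


@pytest.fixture
def small_bundle(small_scenario):
    expr, truth, tfs = simulate_grn(small_scenario)
    triples, markers = simulate_kg(truth, small_scenario)
    kg = kg_from_triples(triples, expression_genes=expr.gene_ids)
    return {"expr": expr, "truth": truth, "tfs": tfs, "kg": kg,
            "markers": markers, "scenario": small_scenario}
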