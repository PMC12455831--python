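"""Cell type-specific knowledge graph construction.

Pathway relations (KEGG KGML dialect) are parsed into (head, relation,
tail) triples. Only the "PPrel" (protein–protein) and "GErel" (gene
expression) relation elements are used, and their subtypes are mapped
onto three coarse categories:

* positive — activation, expression
* negative — inhibition, repression
* uncertain — (de)phosphorylation, glycosylation, ubiquitination,
  methylation

Subtypes carrying no direct regulatory meaning (indirect effect, state
change, binding/association, dissociation, missing interaction) are
excluded, as are unknown subtype strings.

The base graph is filtered to a cell type by keeping marker genes plus
their first-order neighbors (edge direction ignored for neighborhood),
then entities are partitioned against the single-cell gene set into
E_scg (present in the expression data) and E_kgg (knowledge-graph
only), which determines each triple's corruption scheme during
embedding training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .data_io import EdgeSet, normalize_gene_id

logger = logging.getLogger("kgrn")

__all__ = [
    "RELATION_CATEGORIES",
    "EXCLUDED",
    "Triple",
    "KnowledgeGraph",
    "parse_kgml",
    "categorize_relation",
    "build_knowledge_graph",
    "filter_by_markers",
    "partition_entities",
    "kg_overlap_with_truth",
    "read_triples",
    "write_triples",
]

RELATION_CATEGORIES = ("positive", "negative", "uncertain")
EXCLUDED = "EXCLUDED"

_SUBTYPE_MAP = {
    "activation": "positive",
    "expression": "positive",
    "inhibition": "negative",
    "repression": "negative",
    "dephosphorylation": "uncertain",
    "phosphorylation": "uncertain",
    "glycosylation": "uncertain",
    "ubiquitination": "uncertain",
    "methylation": "uncertain",
}
_KNOWN_EXCLUDED = {
    "indirect effect",
    "state change",
    "binding/association",
    "dissociation",
    "missing interaction",
}


@dataclass(frozen=True)
class Triple:
    """(head, relation-category, tail) — the knowledge graph's atomic fact."""

    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if self.relation not in RELATION_CATEGORIES:
            raise ValueError(f"unknown relation category {self.relation!r}")


@dataclass
class KnowledgeGraph:
    """Entities and categorized triples, optionally partitioned.

    After :func:`partition_entities`, `scg_entities` / `kgg_entities`
    split E into genes present in / absent from the expression data and
    `triple_class` maps each triple to scg_scg / scg_kgg / other.
    """

    entities: set[str] = field(default_factory=set)
    triples: set[Triple] = field(default_factory=set)
    scg_entities: set[str] = field(default_factory=set)
    kgg_entities: set[str] = field(default_factory=set)
    triple_class: dict[Triple, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.triples)

    def undirected_pairs(self) -> set[frozenset]:
        return {frozenset((t.head, t.tail)) for t in self.triples
                if t.head != t.tail}


def categorize_relation(subtype: str) -> str:
    """Map a KGML relation subtype to a coarse category or EXCLUDED."""
    key = str(subtype).strip().lower()
    if key in _SUBTYPE_MAP:
        return _SUBTYPE_MAP[key]
    if key not in _KNOWN_EXCLUDED:
        logger.warning("unknown relation subtype %r excluded", subtype)
    return EXCLUDED


def _entry_genes(entry, entries_by_id: dict) -> list[str]:
    """Expand a KGML entry to its member gene names.

    Gene entries may list several space-separated names; group entries
    are expanded through their components.
    """
    etype = entry.get("type", "")
    if etype == "group":
        genes: list[str] = []
        for comp in entry.findall("component"):
            member = entries_by_id.get(comp.get("id"))
            if member is not None:
                genes.extend(_entry_genes(member, entries_by_id))
        return genes
    if etype in ("gene", "compound", "ortholog"):
        return [tok for tok in (entry.get("name") or "").split() if tok]
    return []


def parse_kgml(xml_documents: list) -> list[tuple[str, str, str]]:
    """Parse KGML documents into raw (gene_a, subtype, gene_b) records.

    Accepts file paths or XML strings/bytes. Only PPrel and GErel
    relations are emitted; group entries are expanded to their member
    genes (cartesian expansion on both sides of a relation). Each
    subtype element of a relation yields one record.
    """
    records: list[tuple[str, str, str]] = []
    for doc in xml_documents:
        label = str(doc)
        try:
            if isinstance(doc, (str, Path)) and Path(str(doc)).exists():
                tree = etree.parse(str(doc))
                root = tree.getroot()
            else:
                data = doc.encode() if isinstance(doc, str) else doc
                root = etree.fromstring(data)
        except (etree.XMLSyntaxError, OSError, ValueError) as exc:
            raise ValueError(f"malformed KGML document {label[:80]}: {exc}") from exc
        entries_by_id = {e.get("id"): e for e in root.findall("entry")}
        for rel in root.findall("relation"):
            if rel.get("type") not in ("PPrel", "GErel"):
                continue
            e1 = entries_by_id.get(rel.get("entry1"))
            e2 = entries_by_id.get(rel.get("entry2"))
            if e1 is None or e2 is None:
                continue
            heads = _entry_genes(e1, entries_by_id)
            tails = _entry_genes(e2, entries_by_id)
            for sub in rel.findall("subtype"):
                name = sub.get("name", "")
                for h in heads:
                    for t in tails:
                        records.append((h, name, t))
    return records


def build_knowledge_graph(records: list[tuple[str, str, str]],
                          id_mode: str = "casefold") -> KnowledgeGraph:
    """Categorize raw relation records into a deduplicated KnowledgeGraph."""
    triples: set[Triple] = set()
    n_seen = 0
    for h, subtype, t in records:
        cat = categorize_relation(subtype)
        if cat == EXCLUDED:
            continue
        n_seen += 1
        triples.add(Triple(normalize_gene_id(h, id_mode), cat,
                           normalize_gene_id(t, id_mode)))
    n_dup = n_seen - len(triples)
    if n_dup:
        logger.info("collapsed %d duplicate triples (multi-pathway)", n_dup)
    entities = {t.head for t in triples} | {t.tail for t in triples}
    return KnowledgeGraph(entities=entities, triples=triples)


def filter_by_markers(kg: KnowledgeGraph, markers: list[str],
                      id_mode: str = "casefold") -> KnowledgeGraph:
    """Restrict the graph to marker genes and their first-order neighbors.

    Neighborhood treats triples as undirected: a marker's regulators and
    its targets are both retained. The result is the induced subgraph on
    the retained node set.
    """
    marker_keys = {normalize_gene_id(m, id_mode) for m in markers}
    present = marker_keys & kg.entities
    if not present:
        raise ValueError(
            "no marker gene matches a knowledge-graph entity — "
            "check marker list / gene-id conventions"
        )
    retained = set(present)
    for t in kg.triples:
        if t.head in present:
            retained.add(t.tail)
        if t.tail in present:
            retained.add(t.head)
    kept = {t for t in kg.triples if t.head in retained and t.tail in retained}
    entities = {t.head for t in kept} | {t.tail for t in kept}
    # markers without any surviving triple still count as entities
    entities |= present
    return KnowledgeGraph(entities=entities, triples=kept)


def partition_entities(kg: KnowledgeGraph, expression_genes,
                       id_mode: str = "casefold") -> KnowledgeGraph:
    """Partition entities into E_scg / E_kgg and classify every triple.

    A triple is scg_scg when both endpoints are expression genes,
    scg_kgg when its tail is knowledge-graph-only, and "other" when the
    head alone is knowledge-graph-only (kept in training with tail-only
    corruption).
    """
    expr_keys = {normalize_gene_id(g, id_mode) for g in expression_genes}
    scg = kg.entities & expr_keys
    kgg = kg.entities - expr_keys
    classes: dict[Triple, str] = {}
    for t in kg.triples:
        if t.head in scg and t.tail in scg:
            classes[t] = "scg_scg"
        elif t.tail in kgg:
            classes[t] = "scg_kgg"
        else:
            classes[t] = "other"
    return KnowledgeGraph(entities=set(kg.entities), triples=set(kg.triples),
                          scg_entities=scg, kgg_entities=kgg,
                          triple_class=classes)


def kg_overlap_with_truth(kg: KnowledgeGraph, truth: EdgeSet) -> float:
    """Fraction (percent) of undirected KG gene pairs present in the truth."""
    kg_pairs = kg.undirected_pairs()
    if not kg_pairs:
        raise ValueError("knowledge graph has no gene pairs")
    if not truth.edges:
        raise ValueError("ground-truth edge set is empty")
    truth_pairs = truth.undirected_pairs()
    return 100.0 * len(kg_pairs & truth_pairs) / len(kg_pairs)


def read_triples(path, id_mode: str = "casefold") -> KnowledgeGraph:
    """Read a head/relation/tail TSV into a KnowledgeGraph."""
    triples: set[Triple] = set()
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if [c.lower() for c in header[:3]] != ["head", "relation", "tail"]:
            raise ValueError(f"triple TSV {path} must have header head\\trelation\\ttail")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            h, r, t = parts[:3]
            if r not in RELATION_CATEGORIES:
                raise ValueError(f"{path}:{ln}: unknown relation {r!r}")
            triples.add(Triple(normalize_gene_id(h, id_mode), r,
                               normalize_gene_id(t, id_mode)))
    entities = {t.head for t in triples} | {t.tail for t in triples}
    return KnowledgeGraph(entities=entities, triples=triples)


def write_triples(kg: KnowledgeGraph, path) -> None:
    """Write triples as a sorted head/relation/tail TSV."""
    with open(path, "w") as fh:
        fh.write("head\trelation\ttail\n")
        for t in sorted(kg.triples, key=lambda x: (x.head, x.relation, x.tail)):
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")
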