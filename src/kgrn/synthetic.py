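"""Synthetic fixtures: a planted regulatory network, an expression
matrix consistent with it, and a knowledge graph of tunable fidelity.

The generative model is linear-Gaussian: transcription-factor (TF)
activities are i.i.d. standard normal across cells; each target gene is
a beta-weighted sum of a few randomly chosen TF activities plus
Gaussian noise, and the whole matrix is shifted to non-negative. The
planted truth is the set of TF -> target edges. The companion knowledge
graph mixes a controllable fraction of true edges ("positive" triples)
with random pairs, optionally introducing entities absent from the
expression data so the E_kgg machinery is exercised; markers are a
random subset of TFs so marker filtering retains regulatory hubs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_io import EdgeSet, ExpressionMatrix, write_expression

__all__ = ["SyntheticScenario", "simulate_grn", "simulate_kg", "end_to_end_fixture"]


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic benchmark run."""

    n_tfs: int = 10
    n_targets: int = 100
    n_cells: int = 100
    edges_per_target: int = 2
    effect_size: float = 2.0      # beta
    noise_sd: float = 0.5
    kg_fidelity: float = 0.3      # fraction of KG triples drawn from the truth
    kg_extra_entities: int = 20   # KG-only genes (populate E_kgg)
    kg_n_triples: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tfs, self.n_targets, self.n_cells,
               self.edges_per_target) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.kg_fidelity <= 1:
            raise ValueError("kg_fidelity must lie in [0, 1]")
        if self.edges_per_target > self.n_tfs:
            raise ValueError("edges_per_target cannot exceed n_tfs")


def _gene_names(sc: SyntheticScenario) -> tuple[list[str], list[str]]:
    wt = len(str(sc.n_tfs))
    wg = len(str(sc.n_targets))
    tfs = [f"TF{i + 1:0{wt}d}" for i in range(sc.n_tfs)]
    targets = [f"G{i + 1:0{wg}d}" for i in range(sc.n_targets)]
    return tfs, targets


def simulate_grn(sc: SyntheticScenario) -> tuple[ExpressionMatrix, EdgeSet, list[str]]:
    """Generate (expression matrix, planted truth, TF list)."""
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 11]))
    tfs, targets = _gene_names(sc)
    tf_act = rng.standard_normal((sc.n_tfs, sc.n_cells))
    target_expr = np.empty((sc.n_targets, sc.n_cells))
    edges: set[tuple[str, str]] = set()
    for j, tgt in enumerate(targets):
        regs = rng.choice(sc.n_tfs, size=sc.edges_per_target, replace=False)
        signal = sc.effect_size * tf_act[regs].sum(axis=0)
        noise = sc.noise_sd * rng.standard_normal(sc.n_cells)
        target_expr[j] = signal + noise
        for r in regs:
            edges.add((tfs[r], tgt))
    values = np.vstack([tf_act, target_expr])
    values = values - values.min()  # shift to non-negative
    expr = ExpressionMatrix(gene_ids=tfs + targets,
                            cell_ids=[f"C{c + 1}" for c in range(sc.n_cells)],
                            values=values, cell_type="synthetic")
    return expr, EdgeSet(edges=edges), tfs


def simulate_kg(truth: EdgeSet, sc: SyntheticScenario
                ) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Generate knowledge-graph triples and a marker list.

    Exactly round(kg_fidelity * kg_n_triples) triples are true edges
    (relation "positive"); the remainder joins random expression genes
    and novel KG-only entities, avoiding planted edges so the overlap
    fraction is exactly the constructed one.
    """
    if not truth.edges:
        raise ValueError("truth edge set is empty")
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 23]))
    tfs, targets = _gene_names(sc)
    extra = [f"KGX{i + 1}" for i in range(sc.kg_extra_entities)]
    n_true = int(round(sc.kg_fidelity * sc.kg_n_triples))
    truth_list = sorted(truth.edges)
    n_true = min(n_true, len(truth_list))
    chosen = rng.choice(len(truth_list), size=n_true, replace=False)
    triples = [(truth_list[i][0], "positive", truth_list[i][1])
               for i in sorted(chosen)]
    truth_pairs = {frozenset(e) for e in truth.edges}
    expr_genes = tfs + targets
    seen = {(h, t) for h, _, t in triples}
    n_noise = sc.kg_n_triples - n_true
    made = 0
    while made < n_noise:
        if extra and (made % 2 == 0 or not expr_genes):
            # anchor a KG-only entity as the tail (exercises E_kgg)
            h = expr_genes[int(rng.integers(len(expr_genes)))]
            t = extra[int(rng.integers(len(extra)))]
        else:
            h = expr_genes[int(rng.integers(len(expr_genes)))]
            t = expr_genes[int(rng.integers(len(expr_genes)))]
        if h == t or (h, t) in seen or frozenset((h, t)) in truth_pairs:
            continue
        rel = ["positive", "negative", "uncertain"][int(rng.integers(3))]
        triples.append((h, rel, t))
        seen.add((h, t))
        made += 1
    n_markers = max(1, sc.n_tfs // 2)
    markers = sorted(rng.choice(tfs, size=n_markers, replace=False).tolist())
    return triples, markers


def end_to_end_fixture(sc: SyntheticScenario, out_dir) -> dict[str, Path]:
    """Write a self-contained run bundle in the formats the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, truth, tfs = simulate_grn(sc)
    triples, markers = simulate_kg(truth, sc)
    paths = {
        "expression": out / "ExpressionData.csv",
        "truth": out / "refNetwork.csv",
        "tfs": out / "tfs.txt",
        "markers": out / "markers.txt",
        "kg": out / "kg_triples.tsv",
        "scenario": out / "scenario.json",
    }
    write_expression(expr, paths["expression"])
    with open(paths["truth"], "w") as fh:
        fh.write("Gene1,Gene2\n")
        for s, t in sorted(truth.edges):
            fh.write(f"{s},{t}\n")
    paths["tfs"].write_text("\n".join(tfs) + "\n")
    paths["markers"].write_text("\n".join(markers) + "\n")
    with open(paths["kg"], "w") as fh:
        fh.write("head\trelation\ttail\n")
        for h, r, t in triples:
            fh.write(f"{h}\t{r}\t{t}\n")
    paths["scenario"].write_text(json.dumps(asdict(sc), indent=2) + "\n")
    return paths
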