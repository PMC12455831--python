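"""Readers and writers for the formats the pipeline touches.

Expression matrices follow the BEELINE ``ExpressionData.csv`` dialect
(gene rows, cell columns, header row of cell ids, first column gene
ids). Ground-truth networks are two-column ``Gene1,Gene2`` CSVs; marker
and transcription-factor lists are one-symbol-per-line text files;
ranked-edge output is a four-column TSV.

Gene identifiers coming from pathway databases and single-cell row
names frequently differ only in capitalisation (mouse ``Mafa`` vs KEGG
``MAFA``), so all cross-source joins use a casefolded key by default
while the display form is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("kgrn")

__all__ = [
    "ExpressionMatrix",
    "EdgeSet",
    "normalize_gene_id",
    "read_expression",
    "write_expression",
    "read_ground_truth",
    "read_gene_list",
    "write_ranked_edges",
]


def normalize_gene_id(raw: str, mode: str = "casefold") -> str:
    """Normalize a gene symbol for use as a join key.

    ``exact`` trims surrounding whitespace; ``casefold`` additionally
    upper-cases, producing the key used to match symbols across
    expression data, knowledge graphs and marker lists. The display
    form of an identifier is never altered by callers — casefolded ids
    are join keys only.
    """
    if mode not in ("exact", "casefold"):
        raise ValueError(f"unknown normalization mode: {mode!r}")
    trimmed = str(raw).strip()
    if not trimmed:
        raise ValueError("empty or whitespace-only gene id")
    return trimmed.upper() if mode == "casefold" else trimmed


@dataclass
class ExpressionMatrix:
    """Gene × cell expression matrix with identifiers.

    `values` has one row per gene (the node-feature convention: each
    gene's feature vector is its expression profile across cells).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    cell_type: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes × {len(self.cell_ids)} cells"
            )
        keys = [normalize_gene_id(g, "exact") for g in self.gene_ids]
        if len(set(keys)) != len(keys):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate gene ids: {', '.join(dups)}")
        self.gene_ids = keys

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class EdgeSet:
    """A set of directed (source, target) gene pairs, optionally weighted."""

    edges: set[tuple[str, str]] = field(default_factory=set)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def undirected_pairs(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_expression(path, transpose: bool = False, sep: str | None = None,
                    cell_type: str = "", log1p: bool = False) -> ExpressionMatrix:
    """Read an expression CSV/TSV into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    transpose
        Set when the file is cell rows × gene columns; the result always
        has genes as rows.
    log1p
        Optionally apply log(1+x) to the values (off by default; BEELINE
        matrices arrive pre-processed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    if transpose:
        df = df.T
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {v!r} at data row {i}, column {j} in {path}"
                    ) from None
        raise
    if np.isnan(values).all(axis=1).any():
        bad = [g for g, r in zip(df.index, np.isnan(values).all(axis=1)) if r]
        raise ValueError(f"all-missing expression rows for genes: {bad}")
    if log1p:
        values = np.log1p(values)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        values=values,
        cell_type=cell_type,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write the BEELINE-dialect CSV (exact round-trip partner of read)."""
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
    df.to_csv(path, float_format="%.17g")


def read_ground_truth(path, sep: str | None = None) -> EdgeSet:
    """Read a two-column Gene1,Gene2 edge list as directed edges."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ground-truth file not found: {path}")
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    cols = {c.strip().lower(): c for c in df.columns}
    if "gene1" not in cols or "gene2" not in cols:
        raise ValueError(
            f"ground-truth file {path} must have columns Gene1,Gene2; got {list(df.columns)}"
        )
    pairs = [(normalize_gene_id(a, "exact"), normalize_gene_id(b, "exact"))
             for a, b in zip(df[cols["gene1"]], df[cols["gene2"]])]
    edges = set(pairs)
    n_dup = len(pairs) - len(edges)
    if n_dup:
        logger.info("collapsed %d duplicate ground-truth edges", n_dup)
    return EdgeSet(edges=edges)


def read_gene_list(path) -> list[str]:
    """Read one gene symbol per line, order-preserving, de-duplicated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    out: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g:
                continue
            if g in seen:
                n_dup += 1
                continue
            seen.add(g)
            out.append(g)
    if n_dup:
        logger.warning("dropped %d duplicate entries from %s", n_dup, path)
    return out


def write_ranked_edges(gene_ids: list[str], weights: np.ndarray, path,
                       top_k: int | None = None) -> None:
    """Write edges ranked by weight to a TSV (source, target, weight, rank).

    Self-edges are excluded; ties are broken by (source, target)
    lexicographic order. Ranking uses full precision; weights are
    written with 6 significant digits.
    """
    weights = np.asarray(weights, dtype=np.float64)
    n = len(gene_ids)
    if weights.shape != (n, n):
        raise ValueError(f"weight matrix shape {weights.shape} != ({n}, {n})")
    rows = [(gene_ids[i], gene_ids[j], weights[i, j])
            for i in range(n) for j in range(n) if i != j]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    if top_k is not None:
        rows = rows[:top_k]
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\trank\n")
        for rank, (s, t, w) in enumerate(rows, start=1):
            fh.write(f"{s}\t{t}\t{w:.6g}\t{rank}\n")


def read_ranked_edges(path) -> pd.DataFrame:
    """Read a ranked-edge TSV written by :func:`write_ranked_edges`."""
    df = pd.read_csv(path, sep="\t")
    needed = {"source", "target", "weight"}
    if not needed.issubset(df.columns):
        raise ValueError(f"ranked-edge file {path} missing columns {needed - set(df.columns)}")
    return df
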