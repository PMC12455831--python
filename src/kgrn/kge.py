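"""Knowledge-graph embedding: ComplEx scoring and contrastive loss.

Entities and relations are complex-valued vectors; the plausibility of
a triple (h, r, t) is the ComplEx score

    d_r(h, t) = Re( h^T diag(r) conj(t) )

which, written over real/imaginary parts, expands to

    sum_k Re(h)Re(r)Re(t) + Re(h)Im(r)Im(t) + Im(h)Re(r)Im(t)
          - Im(h)Im(r)Re(t).

Training contrasts each observed triple against n corrupted triples:

    L = -log sigma(d(h,t)) - (1/n) sum_i log sigma(-d(h'_i, t'_i))

averaged over the triple batch. Corruption depends on the triple class:
scg_scg triples corrupt head or tail (fair coin) within E_scg; scg_kgg
(and "other") triples corrupt only the tail within E_kgg. A corrupted
triple identical to its source is rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .knowledge_graph import KnowledgeGraph, Triple

__all__ = [
    "DEFAULT_N_NEGATIVES",
    "NegativeSampleBatch",
    "complex_score",
    "complex_score_batch",
    "sample_negatives",
    "kge_loss",
]

DEFAULT_N_NEGATIVES = 5


def complex_score(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """ComplEx score Re(h^T diag(r) conj(t)) for complex vectors."""
    h = np.asarray(h, dtype=np.complex128)
    r = np.asarray(r, dtype=np.complex128)
    t = np.asarray(t, dtype=np.complex128)
    if not (h.shape == r.shape == t.shape) or h.ndim != 1:
        raise ValueError(f"embedding length mismatch: {h.shape}, {r.shape}, {t.shape}")
    return float(np.sum(h * r * np.conj(t)).real)


def complex_score_batch(H: Tensor, R: Tensor, T: Tensor) -> Tensor:
    """Batched differentiable ComplEx score.

    Each argument is (B, 2*dc) with the first dc columns the real part
    and the last dc the imaginary part; returns a (B,) tensor.
    """
    dc = H.shape[1] // 2
    sl_r = (slice(None), slice(None, dc))
    sl_i = (slice(None), slice(dc, None))
    hr, hi = H[sl_r], H[sl_i]
    rr, ri = R[sl_r], R[sl_i]
    tr, ti = T[sl_r], T[sl_i]
    return (hr * rr * tr + hr * ri * ti + hi * rr * ti - hi * ri * tr).sum(axis=1)


@dataclass
class NegativeSampleBatch:
    """Corrupted triples for one positive, with the replaced slot."""

    source: Triple
    negatives: list[Triple]
    replaced: list[str]  # "head" or "tail" per negative

    def __post_init__(self):
        for neg, slot in zip(self.negatives, self.replaced):
            if neg == self.source:
                raise ValueError("corrupted triple equals its source")
            same_head = neg.head == self.source.head
            same_tail = neg.tail == self.source.tail
            if slot == "head" and (same_head or not same_tail):
                raise ValueError("head-corrupted triple must differ only in head")
            if slot == "tail" and (same_tail or not same_head):
                raise ValueError("tail-corrupted triple must differ only in tail")


def _draw_replacement(pool: list[str], avoid: str, rng: np.random.Generator) -> str:
    if len(pool) < 2 and (len(pool) == 0 or pool[0] == avoid):
        raise ValueError("replacement pool too small for negative sampling")
    while True:
        cand = pool[int(rng.integers(len(pool)))]
        if cand != avoid:
            return cand


def sample_negatives(triple: Triple, kg: KnowledgeGraph, n: int,
                     seed: int | np.random.Generator) -> NegativeSampleBatch:
    """Draw n corrupted triples for one positive.

    The replacement pool and slot follow the triple's class (see module
    docstring). Pools are iterated in sorted entity order so sampling is
    reproducible under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cls = kg.triple_class.get(triple)
    if cls is None:
        raise ValueError(f"triple {triple} not classified — partition the KG first")
    scg_pool = sorted(kg.scg_entities)
    kgg_pool = sorted(kg.kgg_entities)
    negatives: list[Triple] = []
    replaced: list[str] = []
    for _ in range(n):
        if cls == "scg_scg":
            slot = "head" if rng.random() < 0.5 else "tail"
            if slot == "head":
                h = _draw_replacement(scg_pool, triple.head, rng)
                negatives.append(Triple(h, triple.relation, triple.tail))
            else:
                t = _draw_replacement(scg_pool, triple.tail, rng)
                negatives.append(Triple(triple.head, triple.relation, t))
            replaced.append(slot)
        else:  # scg_kgg and "other": tail-only corruption within E_kgg
            t = _draw_replacement(kgg_pool, triple.tail, rng)
            negatives.append(Triple(triple.head, triple.relation, t))
            replaced.append("tail")
    return NegativeSampleBatch(source=triple, negatives=negatives, replaced=replaced)


def kge_loss(pos_scores, neg_scores, n: int | None = None):
    """Contrastive loss of the embedding model.

    ``pos_scores`` is length-B; ``neg_scores`` is B×n (one row of
    corrupted-triple scores per positive). Accepts numpy arrays
    (returns float) or Tensors (returns a Tensor). Uses the stable
    identity -log sigma(x) = softplus(-x).
    """
    tensor_mode = isinstance(pos_scores, Tensor) or isinstance(neg_scores, Tensor)
    pos = pos_scores if isinstance(pos_scores, Tensor) else \
        Tensor(np.atleast_1d(np.asarray(pos_scores, dtype=np.float64)))
    neg = neg_scores if isinstance(neg_scores, Tensor) else \
        Tensor(np.atleast_2d(np.asarray(neg_scores, dtype=np.float64)))
    if pos.data.size == 0:
        raise ValueError("empty triple batch")
    if neg.data.ndim != 2 or neg.data.shape[0] != pos.data.shape[0]:
        raise ValueError("neg_scores must be (batch, n) aligned with pos_scores")
    if n is not None and neg.data.shape[1] != n:
        raise ValueError(f"expected {n} negatives per positive, got {neg.data.shape[1]}")
    # -log sigma(pos) + (1/n) sum_i -log sigma(-neg_i), averaged over batch
    loss = ((-pos).softplus() + neg.softplus().mean(axis=1)).mean()
    if tensor_mode:
        return loss
    return float(loss.data)
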