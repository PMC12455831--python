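"""Joint training of the masked autoencoder and the knowledge-graph
embedding, and extraction of the regulatory weight matrix.

The two objectives are tied through shared gene embeddings: the
autoencoder's latent matrix H is passed through a single linear layer
into a shared space, whose rows serve as the (complexified) entity
embeddings of every knowledge-graph entity that is also an expression
gene. Knowledge-graph-only entities get free, randomly initialized
embeddings. One optimizer updates everything against

    L_total = L_MAE + lambda * L_KGE

with lambda = 1 by default. After training, gene embeddings are
projected, squashed to (-1, 1) with tanh, and the regulatory potential
between genes is their dot product — a symmetric N×N weight matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._autodiff import Adam, Parameter, Tensor, concat, gather
from .base_graph import DEFAULT_KNN_K, GeneGraph, build_knn_graph
from .data_io import ExpressionMatrix
from .kge import DEFAULT_N_NEGATIVES, complex_score_batch, kge_loss, sample_negatives
from .knowledge_graph import RELATION_CATEGORIES, KnowledgeGraph, partition_entities
from .mae import (DEFAULT_GAMMA, DEFAULT_LATENT_DIM, DEFAULT_MASK_RATIO,
                  MaeParams, apply_mask, gat_layer_forward, mae_forward,
                  mask_features, sce_loss)

__all__ = [
    "TrainConfig",
    "SharedProjection",
    "ComplexEmbeddingView",
    "EdgeWeightMatrix",
    "ModelState",
    "total_loss",
    "bind_shared_embeddings",
    "train",
    "edge_weights",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyper-parameters of a training run (all seeds derive from `seed`)."""

    lambda_kge: float = 1.0
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    mask_ratio: float = DEFAULT_MASK_RATIO
    knn_k: int = DEFAULT_KNN_K
    gamma: float = DEFAULT_GAMMA
    n_negatives: int = DEFAULT_N_NEGATIVES
    latent_dim: int = DEFAULT_LATENT_DIM
    shared_dim: int = DEFAULT_LATENT_DIM  # projection output; must be even
    encoder_heads: int = 4
    self_loops: bool = True
    kge_scoring: str = "complex"  # reserved hook; only ComplEx is implemented
    device: str = "cpu"  # advisory only

    def __post_init__(self):
        if self.kge_scoring != "complex":
            raise NotImplementedError(
                f"kge_scoring {self.kge_scoring!r} is a reserved hook; "
                "only the ComplEx scorer is implemented")
        if self.lambda_kge < 0:
            raise ValueError("lambda_kge must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.shared_dim % 2:
            raise ValueError("shared_dim must be even (real/imaginary split)")


@dataclass
class SharedProjection:
    """Linear map from the autoencoder latent space to the shared space."""

    weight: Parameter  # latent_dim × shared_dim
    bias: Parameter    # shared_dim

    def __call__(self, H: Tensor) -> Tensor:
        return H @ self.weight + self.bias.reshape(1, -1)

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    @staticmethod
    def init(latent_dim: int, shared_dim: int,
             rng: np.random.Generator) -> "SharedProjection":
        limit = np.sqrt(6.0 / (latent_dim + shared_dim))
        w = rng.uniform(-limit, limit, size=(latent_dim, shared_dim))
        return SharedProjection(weight=Parameter(w),
                                bias=Parameter(np.zeros(shared_dim)))


@dataclass
class ComplexEmbeddingView:
    """Entity embeddings in the shared space, first half real, second half
    imaginary. Expression-gene rows are differentiable views of the
    projected latent matrix; knowledge-graph-only rows are free
    parameters."""

    embeddings: Tensor  # n_entities × shared_dim
    entity_ids: list[str]
    entity_index: dict[str, int]

    def entity_complex(self, entity: str) -> np.ndarray:
        row = self.embeddings.data[self.entity_index[entity]]
        dc = row.size // 2
        return row[:dc] + 1j * row[dc:]


def total_loss(l_mae, l_kge, lambda_kge: float):
    """L_total = L_MAE + lambda * L_KGE (works on floats or Tensors)."""
    return l_mae + float(lambda_kge) * l_kge


def bind_shared_embeddings(H: Tensor, kg: KnowledgeGraph, proj: SharedProjection,
                           gene_index: dict[str, int],
                           kgg_table: Parameter | None = None) -> ComplexEmbeddingView:
    """Assemble the entity-embedding table shared between the two models.

    Every E_scg entity maps (via its gene row in H) to a projected
    latent embedding, so knowledge-graph gradients flow back into the
    encoder; E_kgg entities use rows of the free `kgg_table`.
    """
    scg = sorted(kg.scg_entities)
    kgg = sorted(kg.kgg_entities)
    missing = [e for e in scg if e not in gene_index]
    if missing:
        raise ValueError(f"E_scg entities without an expression row: {missing[:5]}")
    P = proj(H)
    rows = np.array([gene_index[e] for e in scg], dtype=np.intp)
    parts = []
    if len(scg):
        parts.append(gather(P, rows))
    if len(kgg):
        if kgg_table is None or kgg_table.data.shape[0] != len(kgg):
            raise ValueError("kgg_table missing or misaligned with E_kgg")
        parts.append(kgg_table)
    emb = parts[0] if len(parts) == 1 else concat(parts, axis=0)
    entity_ids = scg + kgg
    return ComplexEmbeddingView(embeddings=emb, entity_ids=entity_ids,
                                entity_index={e: i for i, e in enumerate(entity_ids)})


@dataclass
class EdgeWeightMatrix:
    """Symmetric N×N regulatory-potential matrix over expression genes."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape inconsistent with gene ids")


@dataclass
class ModelState:
    """Everything needed to score edges or resume training."""

    gene_ids: list[str]
    graph: GeneGraph
    mae: MaeParams
    proj: SharedProjection
    config: TrainConfig
    kg: KnowledgeGraph | None = None
    kgg_table: Parameter | None = None
    rel_table: Parameter | None = None
    rel_vocab: tuple = RELATION_CATEGORIES
    gene_index: dict[str, int] = field(default_factory=dict)

    def parameters(self) -> list[Parameter]:
        ps = self.mae.parameters() + self.proj.parameters()
        if self.kgg_table is not None:
            ps.append(self.kgg_table)
        if self.rel_table is not None:
            ps.append(self.rel_table)
        return ps


def _encode(X: np.ndarray, adjacency: np.ndarray, mae: MaeParams) -> np.ndarray:
    """Encoder-only forward on unmasked features (no gradients kept)."""
    H = Tensor(np.asarray(X, dtype=np.float64))
    for layer in mae.encoder_layers:
        H = gat_layer_forward(H, adjacency, layer)
    return H.data


def train(expr: ExpressionMatrix, kg: KnowledgeGraph | None = None,
          cfg: TrainConfig | None = None,
          optimizer_state: dict | None = None
          ) -> tuple[ModelState, list[dict]]:
    """Run joint (or MAE-only, when kg is None) training.

    Each epoch draws a fresh random node mask and — when a knowledge
    graph is supplied and lambda > 0 — fresh negative samples for every
    triple, then takes one full-batch optimizer step on L_total. All
    randomness (initialization, masks, corruption) derives from
    cfg.seed, so runs are exactly reproducible.
    """
    cfg = cfg or TrainConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_mae, s_proj, s_kge, s_mask, s_neg = ss.spawn(5)
    rng_mask = np.random.default_rng(s_mask)
    rng_neg = np.random.default_rng(s_neg)

    graph = build_knn_graph(expr, k=cfg.knn_k, self_loops=cfg.self_loops)
    X = graph.features
    n_cells = X.shape[1]
    mae = MaeParams.init(n_features=n_cells, latent_dim=cfg.latent_dim,
                         encoder_heads=cfg.encoder_heads,
                         rng=np.random.default_rng(s_mae),
                         mask_ratio=cfg.mask_ratio, gamma=cfg.gamma)
    proj = SharedProjection.init(cfg.latent_dim, cfg.shared_dim,
                                 np.random.default_rng(s_proj))
    gene_index = {g: i for i, g in enumerate(graph.gene_ids)}

    kgg_table = rel_table = None
    triples = []
    if kg is not None:
        if not kg.triple_class:
            kg = partition_entities(kg, graph.gene_ids)
        rng_kge = np.random.default_rng(s_kge)
        if kg.kgg_entities:
            kgg_table = Parameter(rng_kge.normal(0.0, 0.1,
                                                 size=(len(kg.kgg_entities),
                                                       cfg.shared_dim)))
        rel_table = Parameter(rng_kge.normal(0.0, 0.1,
                                             size=(len(RELATION_CATEGORIES),
                                                   cfg.shared_dim)))
        triples = sorted(kg.triples, key=lambda t: (t.head, t.relation, t.tail))

    model = ModelState(gene_ids=list(graph.gene_ids), graph=graph, mae=mae,
                       proj=proj, config=cfg, kg=kg, kgg_table=kgg_table,
                       rel_table=rel_table, gene_index=gene_index)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    if optimizer_state is not None:
        opt.load_state_dict(optimizer_state)

    rel_idx_of = {r: i for i, r in enumerate(RELATION_CATEGORIES)}
    use_kge = kg is not None and cfg.lambda_kge > 0 and len(triples) > 0

    history: list[dict] = []
    Xt = Tensor(X)
    for epoch in range(cfg.epochs):
        mask = mask_features(X, cfg.mask_ratio, mae.mask_token.data, rng_mask)
        idx = mask.masked_nodes
        X_masked = apply_mask(Xt, mae.mask_token, idx)
        H, X_rec = mae_forward(X_masked, graph.adjacency, mae, masked_nodes=idx)
        l_mae = sce_loss(Xt, X_rec, idx, cfg.gamma) if len(idx) else Tensor(0.0)

        if use_kge:
            view = bind_shared_embeddings(H, kg, proj, gene_index, kgg_table)
            eidx = view.entity_index
            head_i, tail_i, rel_i = [], [], []
            nh, nt, nr = [], [], []
            for t in triples:
                head_i.append(eidx[t.head])
                tail_i.append(eidx[t.tail])
                rel_i.append(rel_idx_of[t.relation])
                batch = sample_negatives(t, kg, cfg.n_negatives, rng_neg)
                for neg in batch.negatives:
                    nh.append(eidx[neg.head])
                    nt.append(eidx[neg.tail])
                    nr.append(rel_idx_of[neg.relation])
            E = view.embeddings
            pos = complex_score_batch(gather(E, head_i), gather(rel_table, rel_i),
                                      gather(E, tail_i))
            neg = complex_score_batch(gather(E, nh), gather(rel_table, nr),
                                      gather(E, nt))
            l_kge = kge_loss(pos, neg.reshape(len(triples), cfg.n_negatives),
                             cfg.n_negatives)
        else:
            l_kge = Tensor(0.0)

        l_total = total_loss(l_mae, l_kge, cfg.lambda_kge)
        if not np.isfinite(l_total.data):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        opt.zero_grad()
        l_total.backward()
        opt.step()
        history.append({"epoch": epoch, "l_mae": float(l_mae.data),
                        "l_kge": float(l_kge.data),
                        "l_total": float(l_total.data)})
    model._opt_state = opt.state_dict()  # type: ignore[attr-defined]
    return model, history


def edge_weights(model: ModelState) -> EdgeWeightMatrix:
    """Regulatory-potential matrix W = tanh(Z) tanh(Z)^T.

    Z is the projected shared-space embedding of every expression gene,
    computed from an unmasked encoder pass. W is symmetric; its
    diagonal is reported but excluded from all rankings downstream.
    """
    H = _encode(model.graph.features, model.graph.adjacency, model.mae)
    Z = np.tanh(H @ model.proj.weight.data + model.proj.bias.data)
    return EdgeWeightMatrix(gene_ids=list(model.gene_ids), weights=Z @ Z.T)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: ModelState, path, history: list[dict] | None = None) -> None:
    """Serialize the full model (and optimizer state) to one .npz file."""
    arrays: dict[str, np.ndarray] = {
        "format_version": np.array([1]),
        "features": model.graph.features,
        "adjacency": model.graph.adjacency,
        "gene_ids": np.array(model.gene_ids, dtype=object),
        "mask_token": model.mae.mask_token.data,
        "proj_w": model.proj.weight.data,
        "proj_b": model.proj.bias.data,
    }
    for tag, layers in (("enc", model.mae.encoder_layers),
                        ("dec", model.mae.decoder_layers)):
        for i, lyr in enumerate(layers):
            arrays[f"{tag}{i}_w"] = lyr.weight.data
            arrays[f"{tag}{i}_a"] = lyr.attn_vector.data
            arrays[f"{tag}{i}_alpha"] = lyr.prelu_alpha.data
            arrays[f"{tag}{i}_meta"] = np.array(
                [lyr.heads, int(lyr.average_heads),
                 1 if lyr.activation == "prelu" else 0, lyr.negative_slope])
    if model.kgg_table is not None:
        arrays["kgg_table"] = model.kgg_table.data
    if model.rel_table is not None:
        arrays["rel_table"] = model.rel_table.data
    if model.kg is not None:
        arrays["kg_triples"] = np.array(
            [[t.head, t.relation, t.tail, model.kg.triple_class.get(t, "")]
             for t in sorted(model.kg.triples,
                             key=lambda x: (x.head, x.relation, x.tail))],
            dtype=object).reshape(-1, 4)
        arrays["kg_scg"] = np.array(sorted(model.kg.scg_entities), dtype=object)
        arrays["kg_kgg"] = np.array(sorted(model.kg.kgg_entities), dtype=object)
    arrays["config_json"] = np.array([json.dumps(asdict(model.config))], dtype=object)
    opt_state = getattr(model, "_opt_state", None)
    if opt_state is not None:
        arrays["opt_t"] = np.array([opt_state["t"]])
        for i, (m, v) in enumerate(zip(opt_state["m"], opt_state["v"])):
            arrays[f"opt_m{i}"] = m
            arrays[f"opt_v{i}"] = v
    if history is not None:
        arrays["history"] = np.array(
            [[h["epoch"], h["l_mae"], h["l_kge"], h["l_total"]] for h in history])
    np.savez(path, **arrays)


def _load_layer(data, tag, i, k_feats):
    from .mae import GatLayerParams
    meta = data[f"{tag}{i}_meta"]
    lyr = GatLayerParams(
        weight=Parameter(data[f"{tag}{i}_w"]),
        attn_vector=Parameter(data[f"{tag}{i}_a"]),
        heads=int(meta[0]),
        activation="prelu" if int(meta[2]) else "identity",
        negative_slope=float(meta[3]),
        average_heads=bool(int(meta[1])),
        prelu_alpha=Parameter(data[f"{tag}{i}_alpha"]),
    )
    return lyr


def load_checkpoint(path) -> tuple[ModelState, dict | None]:
    """Reload a checkpoint; `edge_weights` on the result is bit-identical
    to the model that was saved."""
    from .knowledge_graph import Triple
    with np.load(path, allow_pickle=True) as data:
        cfg = TrainConfig(**json.loads(str(data["config_json"][0])))
        enc, dec = [], []
        i = 0
        while f"enc{i}_w" in data:
            enc.append(_load_layer(data, "enc", i, None))
            i += 1
        i = 0
        while f"dec{i}_w" in data:
            dec.append(_load_layer(data, "dec", i, None))
            i += 1
        mae = MaeParams(encoder_layers=enc, decoder_layers=dec,
                        mask_token=Parameter(data["mask_token"]),
                        mask_ratio=cfg.mask_ratio, gamma=cfg.gamma,
                        latent_dim=cfg.latent_dim)
        proj = SharedProjection(weight=Parameter(data["proj_w"]),
                                bias=Parameter(data["proj_b"]))
        gene_ids = [str(g) for g in data["gene_ids"]]
        graph = GeneGraph(gene_ids=gene_ids, adjacency=data["adjacency"],
                          features=data["features"], k_used=cfg.knn_k)
        kg = None
        if "kg_triples" in data:
            rows = data["kg_triples"]
            triples = {Triple(str(r[0]), str(r[1]), str(r[2])) for r in rows}
            classes = {Triple(str(r[0]), str(r[1]), str(r[2])): str(r[3])
                       for r in rows}
            kg = KnowledgeGraph(
                entities={t.head for t in triples} | {t.tail for t in triples},
                triples=triples,
                scg_entities={str(e) for e in data["kg_scg"]},
                kgg_entities={str(e) for e in data["kg_kgg"]},
                triple_class=classes)
        model = ModelState(
            gene_ids=gene_ids, graph=graph, mae=mae, proj=proj, config=cfg,
            kg=kg,
            kgg_table=Parameter(data["kgg_table"]) if "kgg_table" in data else None,
            rel_table=Parameter(data["rel_table"]) if "rel_table" in data else None,
            gene_index={g: i for i, g in enumerate(gene_ids)})
        opt_state = None
        if "opt_t" in data:
            m, v = [], []
            i = 0
            while f"opt_m{i}" in data:
                m.append(data[f"opt_m{i}"])
                v.append(data[f"opt_v{i}"])
                i += 1
            opt_state = {"t": int(data["opt_t"][0]), "m": m, "v": v}
            model._opt_state = opt_state  # type: ignore[attr-defined]
    return model, opt_state
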