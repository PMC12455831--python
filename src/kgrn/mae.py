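"""Masked graph autoencoder over the base gene graph.

A GAT encoder maps the (partially masked) expression feature matrix to
latent gene embeddings H; a GAT decoder reconstructs the features. The
training signal is the scaled cosine error on the masked nodes:

    L = (1/|V~|) * sum_{i in V~} (1 - cos(x_i, x~_i))^gamma,  gamma >= 1

with gamma = 1 by default (equal weighting of all sample errors).

Attention follows the standard single-layer GAT formulation: the
unnormalized coefficient for edge (i, j) is
LeakyReLU(a^T [W h_i || W h_j]), softmax-normalized over the in-graph
neighborhood of i. Multi-head outputs are concatenated on hidden layers
and averaged on the final decoder layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Parameter, Tensor, concat

__all__ = [
    "GatLayerParams",
    "MaeParams",
    "MaskResult",
    "mask_features",
    "gat_attention_row",
    "gat_layer_forward",
    "mae_forward",
    "sce_loss",
]

DEFAULT_MASK_RATIO = 0.5
DEFAULT_GAMMA = 1.0
DEFAULT_LATENT_DIM = 64
_EPS = 1e-8


# ---------------------------------------------------------------------------
# parameters


@dataclass
class GatLayerParams:
    """One GAT layer: per-head weight matrices and attention vectors.

    weight has shape (heads, in_dim, out_dim); attn_vector has shape
    (heads, 2*out_dim) and is split into source/destination halves.
    `average_heads` selects head-averaging (final decoder layer) instead
    of concatenation. `activation` is "prelu" (learnable scalar slope)
    or "identity".
    """

    weight: Parameter
    attn_vector: Parameter
    heads: int
    activation: str = "prelu"
    negative_slope: float = 0.2
    average_heads: bool = False
    prelu_alpha: Parameter = None  # type: ignore[assignment]

    def __post_init__(self):
        h, in_dim, out_dim = self.weight.data.shape
        if h != self.heads or self.attn_vector.data.shape != (h, 2 * out_dim):
            raise ValueError("inconsistent GAT layer parameter shapes")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.prelu_alpha is None:
            self.prelu_alpha = Parameter(np.array(0.25))

    @property
    def in_dim(self) -> int:
        return self.weight.data.shape[1]

    @property
    def out_dim(self) -> int:
        return self.weight.data.shape[2]

    def parameters(self) -> list[Parameter]:
        ps = [self.weight, self.attn_vector]
        if self.activation == "prelu":
            ps.append(self.prelu_alpha)
        return ps

    @staticmethod
    def init(in_dim: int, out_dim: int, heads: int, rng: np.random.Generator,
             activation: str = "prelu", average_heads: bool = False,
             negative_slope: float = 0.2) -> "GatLayerParams":
        """Xavier-uniform initialization."""
        limit_w = np.sqrt(6.0 / (in_dim + out_dim))
        w = rng.uniform(-limit_w, limit_w, size=(heads, in_dim, out_dim))
        limit_a = np.sqrt(6.0 / (2 * out_dim + 1))
        a = rng.uniform(-limit_a, limit_a, size=(heads, 2 * out_dim))
        return GatLayerParams(weight=Parameter(w), attn_vector=Parameter(a),
                              heads=heads, activation=activation,
                              average_heads=average_heads,
                              negative_slope=negative_slope)


@dataclass
class MaeParams:
    """Encoder/decoder stacks, mask token and loss hyper-parameters."""

    encoder_layers: list[GatLayerParams]
    decoder_layers: list[GatLayerParams]
    mask_token: Parameter
    mask_ratio: float = DEFAULT_MASK_RATIO
    gamma: float = DEFAULT_GAMMA
    latent_dim: int = DEFAULT_LATENT_DIM
    remask: bool = False

    def __post_init__(self):
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if not 0 <= self.mask_ratio <= 1:
            raise ValueError("mask_ratio must lie in [0, 1]")
        enc_out = self.encoder_layers[-1]
        out = enc_out.out_dim if enc_out.average_heads else enc_out.out_dim * enc_out.heads
        if out != self.latent_dim:
            raise ValueError(f"encoder output dim {out} != latent_dim {self.latent_dim}")

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = [self.mask_token]
        for layer in self.encoder_layers + self.decoder_layers:
            ps.extend(layer.parameters())
        return ps

    @staticmethod
    def init(n_features: int, latent_dim: int = DEFAULT_LATENT_DIM,
             encoder_heads: int = 4, rng: np.random.Generator | None = None,
             mask_ratio: float = DEFAULT_MASK_RATIO,
             gamma: float = DEFAULT_GAMMA) -> "MaeParams":
        """Default architecture: 2-layer encoder (multi-head, concatenated),
        1-head single-layer decoder with identity output activation."""
        rng = rng or np.random.default_rng()
        if latent_dim % encoder_heads:
            raise ValueError("latent_dim must be divisible by encoder_heads")
        per_head = latent_dim // encoder_heads
        enc = [
            GatLayerParams.init(n_features, per_head, encoder_heads, rng),
            GatLayerParams.init(latent_dim, per_head, encoder_heads, rng),
        ]
        dec = [GatLayerParams.init(latent_dim, n_features, 1, rng,
                                   activation="identity", average_heads=True)]
        return MaeParams(encoder_layers=enc, decoder_layers=dec,
                         mask_token=Parameter(np.zeros(n_features)),
                         mask_ratio=mask_ratio, gamma=gamma, latent_dim=latent_dim)


# ---------------------------------------------------------------------------
# masking


@dataclass
class MaskResult:
    """Masked feature matrix and the index set of masked nodes."""

    masked_features: np.ndarray
    masked_nodes: np.ndarray  # sorted integer indices

    n_masked: int = field(init=False)

    def __post_init__(self):
        self.n_masked = len(self.masked_nodes)


def mask_features(X: np.ndarray, mask_ratio: float, token: np.ndarray,
                  seed: int | np.random.Generator) -> MaskResult:
    """Replace a random round(mask_ratio * N) subset of rows with the token.

    The subset is drawn uniformly without replacement from the given
    seed (or Generator); unmasked rows are bit-identical to the input.
    """
    if not 0 <= mask_ratio <= 1:
        raise ValueError("mask_ratio must lie in [0, 1]")
    X = np.asarray(X, dtype=np.float64)
    token = np.asarray(token, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = X.shape[0]
    n_mask = int(round(mask_ratio * n))
    idx = np.sort(rng.choice(n, size=n_mask, replace=False))
    out = X.copy()
    out[idx] = token
    return MaskResult(masked_features=out, masked_nodes=idx)


def apply_mask(X: Tensor, token: Parameter, masked_nodes: np.ndarray) -> Tensor:
    """Differentiable masking: masked rows become the (learnable) token."""
    n = X.data.shape[0]
    ind = np.zeros((n, 1))
    ind[masked_nodes] = 1.0
    return X * Tensor(1.0 - ind) + token.reshape(1, -1) * Tensor(ind)


# ---------------------------------------------------------------------------
# attention / forward


def gat_attention_row(h_self: np.ndarray, h_neighbors: list[np.ndarray],
                      params: GatLayerParams) -> np.ndarray:
    """Attention coefficients of one node over its neighbors.

    Returns shape (n_neighbors,) for a single-head layer, else
    (heads, n_neighbors). Coefficients sum to 1 per head.
    """
    if len(h_neighbors) == 0:
        raise ValueError("empty neighborhood (self-loops prevent this in practice)")
    W = params.weight.data
    a = params.attn_vector.data
    out = params.out_dim
    coefs = []
    for h in range(params.heads):
        zi = W[h].T @ np.asarray(h_self, dtype=np.float64)
        logits = []
        for hn in h_neighbors:
            zj = W[h].T @ np.asarray(hn, dtype=np.float64)
            x = a[h, :out] @ zi + a[h, out:] @ zj
            logits.append(x if x > 0 else params.negative_slope * x)
        logits = np.asarray(logits)
        e = np.exp(logits - logits.max())
        coefs.append(e / e.sum())
    coefs = np.asarray(coefs)
    return coefs[0] if params.heads == 1 else coefs


def _masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to mask==1 entries (mask is constant)."""
    # subtracting the detached row max keeps every exponent <= 0
    row_max = logits.data.max(axis=1, keepdims=True)
    m = Tensor(mask.astype(np.float64))
    e = ((logits - Tensor(row_max)) * m).exp() * m
    return e / e.sum(axis=1, keepdims=True)


def gat_layer_forward(H_in: Tensor | np.ndarray, adjacency: np.ndarray,
                      params: GatLayerParams) -> Tensor:
    """One GAT layer on the whole graph.

    h_i' = sigma( sum_{j in N_i} alpha_ij W h_j ), attention per head,
    heads concatenated (or averaged when `average_heads`).
    """
    H = H_in if isinstance(H_in, Tensor) else Tensor(np.asarray(H_in, dtype=np.float64))
    adj = np.asarray(adjacency)
    if (adj.sum(axis=1) == 0).any():
        bad = np.flatnonzero(adj.sum(axis=1) == 0)
        raise ValueError(f"isolated nodes without self-loops: {bad.tolist()}")
    out = params.out_dim
    head_outs = []
    for h in range(params.heads):
        W = Tensor(params.weight.data[h]) if not params.weight.requires_grad \
            else params.weight[h]
        Z = H @ W  # N × out
        a_src = params.attn_vector[h][:out]
        a_dst = params.attn_vector[h][out:]
        s = Z @ a_src  # N
        d = Z @ a_dst  # N
        logits = (s.reshape(-1, 1) + d.reshape(1, -1)).leaky_relu(params.negative_slope)
        alpha = _masked_softmax(logits, adj)
        head_outs.append(alpha @ Z)
    if params.average_heads:
        agg = head_outs[0]
        for ho in head_outs[1:]:
            agg = agg + ho
        agg = agg * (1.0 / params.heads)
    else:
        agg = head_outs[0] if params.heads == 1 else concat(head_outs, axis=1)
    if params.activation == "prelu":
        return agg.prelu(params.prelu_alpha)
    if params.activation == "identity":
        return agg
    raise ValueError(f"unknown activation {params.activation!r}")


def mae_forward(X_masked: Tensor | np.ndarray, adjacency: np.ndarray,
                params: MaeParams,
                masked_nodes: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """Encoder then decoder: H = f_E(X_masked, A), X~ = f_D(H, A).

    No re-masking happens between encoder and decoder unless
    ``params.remask`` is set (off by default), in which case the latent
    rows of the masked nodes are zeroed before decoding.
    """
    H = X_masked if isinstance(X_masked, Tensor) else \
        Tensor(np.asarray(X_masked, dtype=np.float64))
    for layer in params.encoder_layers:
        H = gat_layer_forward(H, adjacency, layer)
    latent = H
    if params.remask and masked_nodes is not None and len(masked_nodes):
        keep = np.ones((H.data.shape[0], 1))
        keep[masked_nodes] = 0.0
        H = H * Tensor(keep)
    for layer in params.decoder_layers:
        H = gat_layer_forward(H, adjacency, layer)
    return latent, H


# ---------------------------------------------------------------------------
# loss


def sce_loss(X, X_rec, masked_nodes, gamma: float = DEFAULT_GAMMA):
    """Scaled cosine error averaged over the masked nodes.

    Accepts numpy arrays (returns a float) or autodiff Tensors (returns
    a Tensor for backprop). Row norms are guarded with a 1e-8 epsilon.
    """
    masked_nodes = np.asarray(masked_nodes, dtype=np.intp)
    if masked_nodes.size == 0:
        raise ValueError("sce_loss requires a nonempty masked-node set")
    tensor_mode = isinstance(X, Tensor) or isinstance(X_rec, Tensor)
    Xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
    Rt = X_rec if isinstance(X_rec, Tensor) else Tensor(np.asarray(X_rec, dtype=np.float64))
    a = Xt[masked_nodes]
    b = Rt[masked_nodes]
    dot = (a * b).sum(axis=1)
    na = ((a * a).sum(axis=1)) ** 0.5
    nb = ((b * b).sum(axis=1)) ** 0.5
    # guard zero rows: max(na*nb, eps), exact for any non-degenerate row
    denom = (na * nb - _EPS).leaky_relu(0.0) + _EPS
    cos = dot / denom
    loss = ((1.0 - cos) ** float(gamma)).mean()
    if tensor_mode:
        return loss
    return float(loss.data)
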