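"""The MORE network: MOHE hypergraph encoders + MOSA attention fusion.

Per modality, a MOHE (multi-omics hypergraph encoder) stacks hypergraph
convolution layers

    X^{(l+1)} = sigma(G X^{(l)} Theta^{(l)} + b^{(l)})

over the shared fused propagation operator G, with dropout between layers
during training, and attaches a linear omics-specific head producing class
logits. The MOSA (multi-omics self-attention) module then treats the I
modality embeddings of each sample as tokens: per head, Q/K/V are affine
maps of the tokens, the I x I attention matrix is the row softmax of
Q K^T / sqrt(d_f), and the aggregated values of all Z heads are
concatenated and flattened into a final linear classifier.

Ablation variants replace the hypergraph encoder with a plain feed-forward
encoder of the same depth (``encoder="nn"``) and/or the attention fusion
with a single feed-forward fusion layer of matching width (``fusion="nn"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, concat, glorot_uniform


@dataclass
class ModelConfig:
    """Architecture hyper-parameters (shared across modalities)."""

    n_layers: int = 2
    embed_dim: int = 64
    n_heads: int = 4
    d_head: int | None = None  # defaults to embed_dim
    dropout: float = 0.5
    leaky_slope: float = 0.25
    encoder: str = "mohe"  # "mohe" | "nn"
    fusion: str = "mosa"  # "mosa" | "nn"

    def head_dim(self) -> int:
        return self.embed_dim if self.d_head is None else self.d_head


def hgnn_layer(
    X: np.ndarray,
    G: np.ndarray,
    theta: np.ndarray,
    bias: np.ndarray | None = None,
    activation: str = "leaky_relu",
    slope: float = 0.25,
) -> np.ndarray:
    """One hypergraph convolution, sigma(G X Theta [+ b]), on plain arrays."""
    out = G @ X @ theta
    if bias is not None:
        out = out + bias
    if activation == "identity":
        return out
    if activation == "leaky_relu":
        return np.where(out > 0, out, slope * out)
    raise ValueError(f"unknown activation {activation!r}")


class MoheEncoder:
    """Hypergraph-convolution encoder + linear omics-specific head."""

    def __init__(self, in_dim: int, cfg: ModelConfig, n_classes: int,
                 rng: np.random.Generator, use_graph: bool = True):
        self.cfg = cfg
        self.use_graph = use_graph
        dims = [in_dim] + [cfg.embed_dim] * cfg.n_layers
        self.thetas = [
            glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(cfg.n_layers)
        ]
        self.biases = [Parameter(np.zeros(dims[i + 1])) for i in range(cfg.n_layers)]
        self.head_w = glorot_uniform(rng, cfg.embed_dim, n_classes)
        self.head_b = Parameter(np.zeros(n_classes))

    def parameters(self) -> list[Parameter]:
        return [*self.thetas, *self.biases, self.head_w, self.head_b]

    def forward(
        self,
        X: Tensor,
        G: Tensor | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Returns (embedding N x embed_dim, omics logits N x n_classes)."""
        h = X
        for layer, (theta, bias) in enumerate(zip(self.thetas, self.biases)):
            if self.use_graph and G is not None:
                h = G @ h
            h = (h @ theta + bias).leaky_relu(self.cfg.leaky_slope)
            if training and layer < len(self.thetas) - 1:
                assert rng is not None
                h = h.dropout(self.cfg.dropout, rng)
        logits = h @ self.head_w + self.head_b
        return h, logits


def mosa_head(
    tokens: np.ndarray,
    w_q: np.ndarray, b_q: np.ndarray,
    w_k: np.ndarray, b_k: np.ndarray,
    w_v: np.ndarray, b_v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Single attention head on one sample's I x embed_dim token stack.

    Returns the I x I attention matrix (rows sum to 1) and the I x d_f
    aggregated values. Plain-array reference used by tests and export.
    """
    q = tokens @ w_q + b_q
    k = tokens @ w_k + b_k
    v = tokens @ w_v + b_v
    d_f = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_f)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    return attn, attn @ v


class MosaFusion:
    """Multi-head self-attention across modality tokens + linear classifier."""

    def __init__(self, n_modalities: int, cfg: ModelConfig, n_classes: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.n_modalities = n_modalities
        d = cfg.embed_dim
        d_f = cfg.head_dim()
        self.heads = []
        for _ in range(cfg.n_heads):
            self.heads.append({
                "w_q": glorot_uniform(rng, d, d_f), "b_q": Parameter(np.zeros(d_f)),
                "w_k": glorot_uniform(rng, d, d_f), "b_k": Parameter(np.zeros(d_f)),
                "w_v": glorot_uniform(rng, d, d_f), "b_v": Parameter(np.zeros(d_f)),
            })
        flat = n_modalities * d_f * cfg.n_heads
        self.clf_w = glorot_uniform(rng, flat, n_classes)
        self.clf_b = Parameter(np.zeros(n_classes))

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for h in self.heads:
            out.extend(h.values())
        out.extend([self.clf_w, self.clf_b])
        return out

    def forward(self, tokens: Tensor) -> tuple[Tensor, list[np.ndarray]]:
        """``tokens``: N x I x embed_dim. Returns (logits N x C, attention).

        The returned attention list holds one N x I x I array per head.
        """
        d_f = self.cfg.head_dim()
        scale = 1.0 / np.sqrt(d_f)
        fused: list[Tensor] = []
        attentions: list[np.ndarray] = []
        for h in self.heads:
            q = tokens @ h["w_q"] + h["b_q"]
            k = tokens @ h["w_k"] + h["b_k"]
            v = tokens @ h["w_v"] + h["b_v"]
            scores = (q @ k.transpose_last()) * scale
            attn = scores.softmax_last()
            attentions.append(attn.data)
            fused.append(attn @ v)  # N x I x d_f
        cat = concat(fused, axis=-1)  # N x I x (d_f * Z)
        n = cat.shape[0]
        flat = cat.reshape(n, self.n_modalities * d_f * self.cfg.n_heads)
        logits = flat @ self.clf_w + self.clf_b
        return logits, attentions


class FeedForwardFusion:
    """Ablation fusion: one linear layer over flattened tokens + classifier.

    Width matches the attention fusion (I * d_f * Z) so the classifier has
    the same shape in both variants.
    """

    def __init__(self, n_modalities: int, cfg: ModelConfig, n_classes: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.n_modalities = n_modalities
        d_f = cfg.head_dim()
        in_dim = n_modalities * cfg.embed_dim
        hidden = n_modalities * d_f * cfg.n_heads
        self.w1 = glorot_uniform(rng, in_dim, hidden)
        self.b1 = Parameter(np.zeros(hidden))
        self.clf_w = glorot_uniform(rng, hidden, n_classes)
        self.clf_b = Parameter(np.zeros(n_classes))

    def parameters(self) -> list[Parameter]:
        return [self.w1, self.b1, self.clf_w, self.clf_b]

    def forward(self, tokens: Tensor) -> tuple[Tensor, list[np.ndarray]]:
        n = tokens.shape[0]
        flat = tokens.reshape(n, self.n_modalities * self.cfg.embed_dim)
        h = (flat @ self.w1 + self.b1).leaky_relu(self.cfg.leaky_slope)
        logits = h @ self.clf_w + self.clf_b
        return logits, []


class MoreModel:
    """Full network: per-modality encoders + cross-modality fusion."""

    def __init__(self, in_dims: list[int], n_classes: int, cfg: ModelConfig,
                 seed: int = 0):
        self.cfg = cfg
        self.n_classes = n_classes
        self.in_dims = list(in_dims)
        rng = np.random.default_rng(seed)
        use_graph = cfg.encoder == "mohe"
        self.encoders = [
            MoheEncoder(d, cfg, n_classes, rng, use_graph=use_graph)
            for d in in_dims
        ]
        if cfg.fusion == "mosa":
            self.fusion: MosaFusion | FeedForwardFusion = MosaFusion(
                len(in_dims), cfg, n_classes, rng
            )
        elif cfg.fusion == "nn":
            self.fusion = FeedForwardFusion(len(in_dims), cfg, n_classes, rng)
        else:
            raise ValueError(f"unknown fusion {cfg.fusion!r}")

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for e in self.encoders:
            out.extend(e.parameters())
        out.extend(self.fusion.parameters())
        return out

    def forward(
        self,
        X_list: list[np.ndarray],
        G: np.ndarray | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[list[Tensor], Tensor, list[np.ndarray]]:
        """Returns (per-omics logits, fused logits, attention matrices)."""
        if len(X_list) != len(self.encoders):
            raise ValueError("one feature matrix per modality required")
        Gt = None if G is None else Tensor(G)
        embeds: list[Tensor] = []
        omics_logits: list[Tensor] = []
        for X, enc in zip(X_list, self.encoders):
            e, lg = enc.forward(Tensor(X), Gt, training=training, rng=rng)
            embeds.append(e)
            omics_logits.append(lg)
        n = embeds[0].shape[0]
        tokens = concat(
            [e.reshape(n, 1, self.cfg.embed_dim) for e in embeds], axis=1
        )
        fused_logits, attn = self.fusion.forward(tokens)
        return omics_logits, fused_logits, attn

    # -- eval-mode conveniences --------------------------------------------

    def predict_logits(
        self, X_list: list[np.ndarray], G: np.ndarray | None
    ) -> tuple[list[np.ndarray], np.ndarray]:
        omics, fused, _ = self.forward(X_list, G, training=False)
        return [o.data for o in omics], fused.data

    def predict_proba(
        self, X_list: list[np.ndarray], G: np.ndarray | None
    ) -> np.ndarray:
        _, fused = self.predict_logits(X_list, G)
        z = fused - fused.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"p{i}"], dtype=np.float64)
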