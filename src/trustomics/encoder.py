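"""Multi-level graph-attention encoder with a Dirichlet evidence head.

Every subject of one omics shares the same binary edge matrix E; only node
features differ, so a whole cohort is encoded as a batched tensor of shape
(n_subjects, d_nodes, f).  One attention head scores each edge (i, j) as

    s_ij = LeakyReLU(a^T [W_C h_i || W_C h_j]),

normalizes the scores over the neighborhood N_i by softmax into attention
coefficients, and aggregates sigma(sum_j alpha_ij W_R h_j); T heads are
concatenated.  Self-loops are always added, so isolated nodes propagate
their own features and every neighborhood is non-empty.

The multi-level structure applies two such layers — G0 -> G1 -> G2 — and
fuses the three levels' node representations (by default flattening and
concatenating them, which preserves node identity for interpretation) into
one subject vector, from which two fully connected layers and a softplus
produce the non-negative per-class evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class EncoderConfig:
    """Architecture hyperparameters of one omics encoder."""

    n_heads: int = 4
    hidden: int = 8
    head_hidden: int = 32       # width of the evidence head's hidden layer
    dropout: float = 0.1
    input_dropout: float = 0.8  # max per-subject masked fraction at train time
    negative_slope: float = 0.2
    readout: str = "flatten"    # or "mean"
    include_level0: bool = True
    n_levels: int = 2

    def __post_init__(self):
        if self.n_heads < 1 or self.hidden < 1:
            raise ValueError("n_heads and hidden must be >= 1")
        if not 0.0 < self.negative_slope < 1.0:
            raise ValueError("negative_slope must lie in (0, 1)")
        if self.readout not in ("flatten", "mean"):
            raise ValueError("readout must be 'flatten' or 'mean'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.input_dropout <= 1.0:
            raise ValueError("input_dropout must lie in [0, 1]")


def _neighbor_mask(edge_matrix: np.ndarray) -> np.ndarray:
    """E with self-loops; the attention support of each node."""
    e = np.asarray(edge_matrix, dtype=np.float64)
    if not np.array_equal(e, e.T):
        raise ValueError("edge matrix must be symmetric")
    m = e.copy()
    np.fill_diagonal(m, 1.0)
    return m


class GATLayer:
    """One multi-head attention layer over a fixed topology."""

    def __init__(self, in_dim: int, n_heads: int, hidden: int,
                 negative_slope: float, rng: np.random.Generator):
        self.in_dim, self.n_heads, self.hidden = in_dim, n_heads, hidden
        self.negative_slope = negative_slope
        self.w_c = nn.parameter(rng, (in_dim, hidden), in_dim, hidden)
        self.w_r = [nn.parameter(rng, (in_dim, hidden), in_dim, hidden)
                    for _ in range(n_heads)]
        self.att = [nn.parameter(rng, (2 * hidden, 1), 2 * hidden, 1)
                    for _ in range(n_heads)]

    @property
    def out_dim(self) -> int:
        return self.n_heads * self.hidden

    def parameters(self):
        return [self.w_c] + self.w_r + self.att

    def _attention_from_wh(self, wh: Tensor, mask: np.ndarray,
                           head: int) -> Tensor:
        a_src = self.att[head][: self.hidden]            # (hidden, 1)
        a_dst = self.att[head][self.hidden:]
        e_src = wh @ a_src                               # (n, d, 1)
        e_dst = (wh @ a_dst).swapaxes(-1, -2)            # (n, 1, d)
        scores = (e_src + e_dst).leaky_relu(self.negative_slope)
        neg = Tensor(-1e9 * (1.0 - mask))                # constant
        att = (scores * Tensor(mask) + neg).softmax(axis=-1)
        return att * Tensor(mask)

    def attention(self, h: Tensor, mask: np.ndarray, head: int) -> Tensor:
        """Attention coefficients of one head: (n, d, d), rows sum to 1."""
        return self._attention_from_wh(h @ self.w_c, mask, head)

    def __call__(self, h: Tensor, mask: np.ndarray) -> Tensor:
        """Batched forward: h (n, d, in_dim) -> (n, d, T * hidden), ELU."""
        wh = h @ self.w_c                                # shared across heads
        heads = []
        for t in range(self.n_heads):
            att = self._attention_from_wh(wh, mask, t)
            agg = att @ (h @ self.w_r[t])                # (n, d, hidden)
            heads.append(agg.elu())
        return nn.concatenate(heads, axis=-1)


def attention_coefficients(node_features: np.ndarray, edge_matrix: np.ndarray,
                           w_c: np.ndarray, att_vec: np.ndarray,
                           negative_slope: float = 0.2) -> np.ndarray:
    """Attention weights of a single-head layer on one graph.

    Reference entry point for inspecting one attention computation:
    ``node_features`` (d, f), ``w_c`` (f, hidden), ``att_vec`` (2 * hidden,).
    Returns the (d, d) matrix of coefficients; row i is the softmax over
    N_i (self-loop included), zero outside the neighborhood.
    """
    layer = GATLayer.__new__(GATLayer)
    hidden = np.asarray(w_c).shape[1]
    layer.in_dim, layer.n_heads, layer.hidden = np.asarray(w_c).shape[0], 1, hidden
    layer.negative_slope = negative_slope
    layer.w_c = Tensor(np.asarray(w_c, dtype=np.float64))
    layer.att = [Tensor(np.asarray(att_vec, dtype=np.float64).reshape(-1, 1))]
    mask = _neighbor_mask(edge_matrix)
    h = Tensor(np.asarray(node_features, dtype=np.float64)[None, :, :])
    return layer.attention(h, mask, 0).data[0]


class EvidenceHead:
    """Two fully connected layers and a softplus produce evidence >= 0."""

    def __init__(self, in_dim: int, hidden: int, k: int,
                 rng: np.random.Generator):
        self.w1 = nn.parameter(rng, (in_dim, hidden), in_dim, hidden)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = nn.parameter(rng, (hidden, k), hidden, k)
        self.b2 = Tensor(np.zeros(k), requires_grad=True)

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        hidden = (x @ self.w1 + self.b1).elu()
        return (hidden @ self.w2 + self.b2).softplus()


class OmicsEncoder:
    """G0 -> G1 -> G2 encoder for one omics block, ending in evidence.

    Holds the fixed topology (edge matrix with self-loops) plus all
    trainable parameters; forward maps a batch of subjects' node features
    to (evidence, logits, fused embedding).
    """

    def __init__(self, n_nodes: int, n_classes: int, edge_matrix: np.ndarray,
                 config: EncoderConfig, rng: np.random.Generator):
        if edge_matrix.shape != (n_nodes, n_nodes):
            raise ValueError("edge matrix does not match node count")
        self.config = config
        self.n_nodes = n_nodes
        self.n_classes = n_classes
        self.mask = _neighbor_mask(edge_matrix)
        self.layers: list[GATLayer] = []
        in_dim = 1
        for _ in range(config.n_levels):
            layer = GATLayer(in_dim, config.n_heads, config.hidden,
                             config.negative_slope, rng)
            self.layers.append(layer)
            in_dim = layer.out_dim
        self.fused_dim = self._fused_dim()
        self.head = EvidenceHead(self.fused_dim, config.head_hidden,
                                 n_classes, rng)
        self.logit_w = nn.parameter(rng, (self.fused_dim, n_classes),
                                    self.fused_dim, n_classes)
        self.logit_b = Tensor(np.zeros(n_classes), requires_grad=True)

    def _fused_dim(self) -> int:
        dims = ([1] if self.config.include_level0 else []) \
            + [layer.out_dim for layer in self.layers]
        per_node = sum(dims)
        return per_node * self.n_nodes if self.config.readout == "flatten" \
            else per_node

    def parameters(self):
        params = []
        for layer in self.layers:
            params += layer.parameters()
        params += self.head.parameters()
        params += [self.logit_w, self.logit_b]
        return params

    def encode(self, values: np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Fused multi-level subject embedding, shape (n, fused_dim)."""
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2 or values.shape[1] != self.n_nodes:
            raise ValueError(
                f"expected (n_subjects, {self.n_nodes}) node features")
        if training and self.config.input_dropout > 0:
            if rng is None:
                raise ValueError("training forward needs an rng for dropout")
            # Masked-ratio augmentation: each subject gets a masking rate
            # drawn uniformly from [0, input_dropout] and that fraction of
            # node features zeroed — deliberately *without* inverted
            # rescaling, since a zero is the scaled minimum, the same
            # "signal removed" state the robustness protocol probes.
            # Training therefore covers every masking level: when the
            # informative features of a subject are gone, the evidential
            # loss can only be satisfied by emitting little evidence, which
            # is what makes the uncertainty mass rise under test-time
            # masking instead of reacting to out-of-distribution zeros.
            rates = rng.uniform(0.0, self.config.input_dropout,
                                size=(values.shape[0], 1))
            keep = rng.random(values.shape) >= rates
            values = values * keep
        h = Tensor(values[:, :, None])                   # G0: (n, d, 1)
        levels = [h] if self.config.include_level0 else []
        for layer in self.layers:
            h = layer(h, self.mask)
            levels.append(h)
        per_node = nn.concatenate(levels, axis=-1)        # (n, d, sum dims)
        n = values.shape[0]
        if self.config.readout == "flatten":
            fused = per_node.reshape(n, self.fused_dim)
        else:
            fused = per_node.mean(axis=1)
        if training and self.config.dropout > 0:
            if rng is None:
                raise ValueError("training forward needs an rng for dropout")
            keep = 1.0 - self.config.dropout
            mask = (rng.random(fused.shape) < keep) / keep
            fused = fused * Tensor(mask)
        return fused

    def __call__(self, values: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None):
        """Forward pass: returns (evidence, logits, fused embedding)."""
        fused = self.encode(values, training=training, rng=rng)
        evidence = self.head(fused)
        logits = fused @ self.logit_w + self.logit_b
        return evidence, logits, fused
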