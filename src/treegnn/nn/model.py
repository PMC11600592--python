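"""The hybrid graph-attention + recurrent architecture.

Pipeline per batch of featurized tree sequences: node embedding (F -> 26),
skip-concat with the raw features, six graph-attention convolution layers
with additive skips + LayerNorm + ReLU, a second skip-concat with the raw
features, a GRU over each tree's node sequence, concatenation of the
12-dim tree summary vector, a GRU over the (padded) sequence of trees, and
an MLP head fed with the hidden state concatenated to the embedded 37-dim
tree-sequence summary vector.  Outputs are raw scores: logits for
classification, z-scores for regression.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import GRU, BatchNorm1d, GATConv, LayerNorm, Linear, Module

TREE_SUMMARY_DIM = 12
GLOBAL_SUMMARY_DIM = 37


# ---------------------------------------------------------------------------
# reference spectral graph convolution (degree-normalized, non-attention)
# ---------------------------------------------------------------------------


def gcn_conv_reference(
    X: np.ndarray, edge_index: np.ndarray, theta: np.ndarray, form: str = "matrix"
) -> np.ndarray:
    """Degree-normalized graph convolution on directed child->parent edges.

    ``matrix`` form computes D^-1/2 (A + I) D^-1/2 X Theta with A_ip = 1 for
    each child->parent edge (messages flow child to parent); ``nodewise``
    evaluates x'_i = Theta^T sum_{j in N(i) ∪ {i}} x_j / sqrt(d_j d_i) with
    N(i) the children of node i and d_i = 1 + |N(i)|.  The two forms agree
    to numerical precision; both are kept as mutual oracles.
    """
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = X.shape[0]
    if X.shape[1] != theta.shape[0]:
        raise ValueError(f"feature dim {X.shape[1]} != theta rows {theta.shape[0]}")
    child = np.asarray(edge_index[0], dtype=np.int64)
    parent = np.asarray(edge_index[1], dtype=np.int64)
    deg = np.ones(n)
    np.add.at(deg, parent, 1.0)  # d_i = 1 + number of children
    if form == "matrix":
        A_hat = np.eye(n)
        A_hat[parent, child] += 1.0  # row = receiver, column = sender
        d_inv_sqrt = np.diag(1.0 / np.sqrt(deg))
        return d_inv_sqrt @ A_hat @ d_inv_sqrt @ X @ theta
    if form == "nodewise":
        out = np.zeros((n, theta.shape[1]))
        children: dict[int, list[int]] = {}
        for c, p in zip(child, parent):
            children.setdefault(int(p), []).append(int(c))
        for i in range(n):
            acc = X[i] / np.sqrt(deg[i] * deg[i])
            for j in children.get(i, ()):
                acc = acc + X[j] / np.sqrt(deg[j] * deg[i])
            out[i] = theta.T @ acc
        return out
    raise ValueError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# functional attention convolution (numpy; the layer shares this math)
# ---------------------------------------------------------------------------


def gat_attention(
    x_i: np.ndarray,
    child_features: np.ndarray,
    theta_s: np.ndarray,
    theta_t: np.ndarray,
    att: np.ndarray,
    negative_slope: float = 0.2,
) -> np.ndarray:
    """Attention weights over {self} ∪ children for a single focal node.

    Returns the softmax over scores a . LeakyReLU(Theta_s x_i + Theta_t x_j),
    the self slot first, then one slot per child.  A leaf (no children)
    trivially gets weight 1 on itself.
    """
    x_i = np.asarray(x_i, dtype=float)
    child_features = np.asarray(child_features, dtype=float).reshape(-1, x_i.shape[0])
    s = theta_s.T @ x_i
    neighbors = np.vstack([x_i[None, :], child_features])
    scores = []
    for j, x_j in enumerate(neighbors):
        pre = s + theta_t.T @ x_j
        act = np.where(pre > 0, pre, negative_slope * pre)
        scores.append(att @ act)
    scores = np.asarray(scores)
    e = np.exp(scores - scores.max())
    return e / e.sum()


def gat_conv(
    X: np.ndarray,
    edge_index: np.ndarray,
    theta_s: np.ndarray,
    theta_t: np.ndarray,
    att: np.ndarray,
    bias: np.ndarray | None = None,
    negative_slope: float = 0.2,
) -> np.ndarray:
    """Full attention-convolution update for every node (numpy forward).

    x'_i = alpha_ii Theta_s x_i + sum_{j in N(i)} alpha_ij Theta_t x_j.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    child = np.asarray(edge_index[0], dtype=np.int64)
    parent = np.asarray(edge_index[1], dtype=np.int64)
    children: dict[int, list[int]] = {}
    for c, p in zip(child, parent):
        children.setdefault(int(p), []).append(int(c))
    out = np.zeros((n, theta_s.shape[1]))
    for i in range(n):
        kids = children.get(i, [])
        alpha = gat_attention(X[i], X[kids] if kids else np.empty((0, X.shape[1])),
                              theta_s, theta_t, att, negative_slope)
        acc = alpha[0] * (theta_s.T @ X[i])
        for w, j in zip(alpha[1:], kids):
            acc = acc + w * (theta_t.T @ X[j])
        out[i] = acc
    if bias is not None:
        out = out + bias
    return out


# ---------------------------------------------------------------------------
# configuration / losses
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureConfig:
    n_node_features: int  # F = 2 + k + 1
    output_size: int = 1  # M
    node_embedding_width: int = 26
    n_conv_layers: int = 6
    tree_hidden: int = 256  # per-tree GRU hidden (H1)
    sequence_hidden: int = 256  # per-sequence GRU hidden (H2)
    head_width: int = 128
    tree_cap: int = 128
    use_graph_conv: bool = True
    use_tree_summary: bool = True
    use_global_summary: bool = True
    global_embedding_width: int = GLOBAL_SUMMARY_DIM  # affine 37 -> 37

    @property
    def conv_width(self) -> int:
        return self.node_embedding_width + self.n_node_features

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureConfig":
        return cls(**json.loads(text))


@dataclass
class LossSpec:
    kind: str  # "categorical_cross_entropy" | "smooth_l1"
    beta: float = 1.0

    def __post_init__(self):
        if self.kind not in ("categorical_cross_entropy", "smooth_l1"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


def loss(predictions, targets, spec: LossSpec):
    """Batch-mean loss; negative cross-entropy for classification.

    Classification targets are integer class indices; regression targets are
    standardized values of the same shape as the predictions.
    """
    pred = predictions if isinstance(predictions, Tensor) else Tensor(np.asarray(predictions, dtype=float))
    if spec.kind == "categorical_cross_entropy":
        targets = np.asarray(targets)
        M = pred.shape[1]
        if targets.max(initial=0) >= M:
            raise ValueError(f"class index {targets.max()} >= number of classes {M}")
        return ad.cross_entropy_logits(pred, targets)
    return ad.smooth_l1(pred, np.asarray(targets, dtype=float), beta=spec.beta)


# ---------------------------------------------------------------------------
# batch container
# ---------------------------------------------------------------------------


@dataclass
class Batch:
    """Flat arrays for a batch of featurized tree sequences.

    All trees in a batch must share a node count (a task has a fixed sample
    size, so every tree has 2n-1 nodes).  Trees are concatenated along a
    flat node axis for the conv block; ``tree_of_sequence`` maps each tree to
    its sequence; ``tree_counts`` give true (un-padded) sequence lengths.
    """

    node_features: np.ndarray  # (total_trees * nodes_per_tree, F)
    edge_index: np.ndarray  # (2, total_edges), rows offset per tree
    nodes_per_tree: int
    tree_counts: np.ndarray  # (B,)
    tree_summaries: np.ndarray  # (total_trees, 12)
    global_summaries: np.ndarray  # (B, 37)
    targets: np.ndarray | None

    @property
    def batch_size(self) -> int:
        return len(self.tree_counts)

    @property
    def total_trees(self) -> int:
        return int(self.tree_counts.sum())


def collate(sequences: Sequence, dtype=np.float64) -> Batch:
    """Assemble FeaturizedSequence objects into a Batch."""
    node_blocks, edge_blocks, summaries, globals_, counts, targets = [], [], [], [], [], []
    nodes_per_tree = None
    offset = 0
    for seq in sequences:
        counts.append(seq.num_trees)
        globals_.append(seq.global_summary)
        summaries.append(seq.tree_summaries)
        if seq.label is not None:
            targets.append(seq.label)
        for nf, ei in zip(seq.node_features, seq.edge_indices):
            if nodes_per_tree is None:
                nodes_per_tree = nf.shape[0]
            elif nf.shape[0] != nodes_per_tree:
                raise ValueError("all trees in a batch must share a node count")
            node_blocks.append(nf)
            edge_blocks.append(ei + offset)
            offset += nodes_per_tree
    target_arr = None
    if targets and len(targets) == len(sequences):
        target_arr = np.asarray(targets, dtype=float)
    return Batch(
        node_features=np.concatenate(node_blocks, axis=0).astype(dtype),
        edge_index=np.concatenate(edge_blocks, axis=1),
        nodes_per_tree=int(nodes_per_tree),
        tree_counts=np.asarray(counts, dtype=np.int64),
        tree_summaries=np.concatenate(summaries, axis=0).astype(dtype),
        global_summaries=np.asarray(globals_, dtype=dtype),
        targets=target_arr,
    )


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class TreeSequenceNet(Module):
    def __init__(self, config: ArchitectureConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        F = config.n_node_features
        self.node_embedding = Linear(F, config.node_embedding_width, rng)
        width = config.conv_width
        self.conv_layers = [GATConv(width, width, rng) for _ in range(config.n_conv_layers)]
        self.conv_norms = [LayerNorm(width) for _ in range(config.n_conv_layers)]
        tree_gru_in = (width + F) if config.use_graph_conv else F
        self.tree_gru = GRU(tree_gru_in, config.tree_hidden, rng)
        seq_in = config.tree_hidden + (TREE_SUMMARY_DIM if config.use_tree_summary else 0)
        self.sequence_gru = GRU(seq_in, config.sequence_hidden, rng)
        head_in = config.sequence_hidden
        if config.use_global_summary:
            self.global_embedding = Linear(GLOBAL_SUMMARY_DIM, config.global_embedding_width, rng)
            head_in += config.global_embedding_width
        else:
            self.global_embedding = None
        self.fc1 = Linear(head_in, config.head_width, rng)
        self.bn1 = BatchNorm1d(config.head_width)
        self.fc2 = Linear(config.head_width, config.head_width, rng)
        self.bn2 = BatchNorm1d(config.head_width)
        self.out = Linear(config.head_width, config.output_size, rng)

    # -- forward -----------------------------------------------------------

    def __call__(self, batch: Batch) -> Tensor:
        cfg = self.config
        dtype = self.node_embedding.weight.data.dtype
        x_raw = Tensor(batch.node_features.astype(dtype))
        total_trees = batch.total_trees
        N = batch.nodes_per_tree

        if cfg.use_graph_conv:
            h = self.node_embedding(x_raw)
            h = ad.concat([h, x_raw], axis=1)
            for conv, norm in zip(self.conv_layers, self.conv_norms):
                h = ad.relu(norm(ad.add(conv(h, batch.edge_index), h)))
            h = ad.concat([h, x_raw], axis=1)
        else:
            h = x_raw

        # per-tree recurrence over the node ordering
        h = ad.reshape(h, (total_trees, N, h.shape[1]))
        tree_vecs = self.tree_gru(h)  # (total_trees, H1)
        if cfg.use_tree_summary:
            tree_vecs = ad.concat([tree_vecs, Tensor(batch.tree_summaries.astype(dtype))], axis=1)

        # pad to (B, T', .) and run the sequence recurrence with true lengths
        B = batch.batch_size
        T_pad = int(batch.tree_counts.max())
        width = tree_vecs.shape[1]
        flat_rows = np.concatenate(
            [t * T_pad + np.arange(c) for t, c in enumerate(batch.tree_counts)]
        )
        padded = ad.scatter_rows(tree_vecs, flat_rows, B * T_pad)
        padded = ad.reshape(padded, (B, T_pad, width))
        seq_vec = self.sequence_gru(padded, lengths=batch.tree_counts)  # (B, H2)

        if cfg.use_global_summary:
            g = self.global_embedding(Tensor(batch.global_summaries.astype(dtype)))
            seq_vec = ad.concat([seq_vec, g], axis=1)

        h = ad.relu(self.bn1(self.fc1(seq_vec)))
        h = ad.relu(self.bn2(self.fc2(h)))
        return self.out(h)

    # -- bookkeeping ---------------------------------------------------------

    def parameter_report(self) -> dict[str, int]:
        return {name: p.data.size for name, p in self.named_parameters()}


def count_parameters(model: Module) -> int:
    """Total learnable scalar count (sum of the itemized report)."""
    return sum(model.parameter_report().values()) if hasattr(model, "parameter_report") else model.num_parameters()


def save_checkpoint(path, model: TreeSequenceNet) -> None:
    """Single container file: layer-named arrays + the JSON config."""
    arrays = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __config__=np.bytes_(model.config.to_json().encode()), **arrays)


def load_checkpoint(path, rng: np.random.Generator | None = None) -> TreeSequenceNet:
    with np.load(path, allow_pickle=False) as data:
        config = ArchitectureConfig.from_json(bytes(data["__config__"]).decode())
        model = TreeSequenceNet(config, rng or np.random.default_rng(0))
        state = {k.replace("/", "."): data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
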