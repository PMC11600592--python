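"""Alignment-CNN comparison path: preprocessing and parameter accounting.

The baseline consumes zero-padded binary genotype matrices whose rows are
ordered by seriation (an approximately minimal open path under cosine
distance) and, for two-population tasks, matched across populations by
optimal assignment.  The network itself is the standard ResNet34 shape;
`baseline_param_count` provides its exact learnable-parameter accounting
for a given input-channel count and output size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


@dataclass
class PaddedAlignment:
    matrix: np.ndarray  # (channels, individuals, W)

    @property
    def width(self) -> int:
        return self.matrix.shape[-1]


@dataclass
class BaselineNetConfig:
    input_channels: int = 1
    output_size: int = 5
    architecture: str = "resnet34-shape"

    def __post_init__(self):
        if self.input_channels < 1 or self.output_size < 1:
            raise ValueError("channels and output size must be >= 1")


# ---------------------------------------------------------------------------
# padding / cropping
# ---------------------------------------------------------------------------


def pad_or_crop(matrix: np.ndarray, width: int) -> np.ndarray:
    """Right-pad with zeros to ``width`` columns, or keep the first ``width``.

    Left-aligned crop: original columns always occupy the leftmost
    positions.  Idempotent at fixed width.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    matrix = np.asarray(matrix)
    n_cols = matrix.shape[-1]
    if n_cols == width:
        return matrix.copy()
    if n_cols > width:
        return matrix[..., :width].copy()
    pad = [(0, 0)] * (matrix.ndim - 1) + [(0, width - n_cols)]
    return np.pad(matrix, pad, mode="constant")


# ---------------------------------------------------------------------------
# seriation
# ---------------------------------------------------------------------------


def cosine_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances; distance to an all-zero row defined as 1."""
    rows = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(rows, axis=1)
    zero = norms == 0
    safe = rows.copy()
    safe[zero] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = cdist(rows, rows, metric="cosine")
    d[np.isnan(d)] = 1.0
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def _path_cost(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def _nearest_neighbor_path(dist: np.ndarray, start: int) -> np.ndarray:
    n = dist.shape[0]
    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(n - 1):
        d = dist[order[-1]].copy()
        d[visited] = np.inf
        nxt = int(d.argmin())
        order.append(nxt)
        visited[nxt] = True
    return np.asarray(order)


def _two_opt(order: np.ndarray, dist: np.ndarray, max_rounds: int = 20) -> np.ndarray:
    """Open-path 2-opt: reverse segments while that reduces the path cost."""
    n = len(order)
    order = order.copy()
    for _ in range(max_rounds):
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                before = 0.0
                after = 0.0
                if i > 0:
                    before += dist[order[i - 1], order[i]]
                    after += dist[order[i - 1], order[j]]
                if j < n - 1:
                    before += dist[order[j], order[j + 1]]
                    after += dist[order[i], order[j + 1]]
                if after < before - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
        if not improved:
            break
    return order


def _exhaustive_path(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:
            continue  # path cost is reversal-symmetric
        cost = _path_cost(np.asarray(perm), dist)
        if cost < best_cost - 1e-12:
            best, best_cost = np.asarray(perm), cost
    return best


def seriate_rows(matrix: np.ndarray, exact_threshold: int = 8) -> np.ndarray:
    """Row permutation approximately minimizing consecutive cosine distance.

    Nearest-neighbor construction from every start plus 2-opt refinement;
    for ``rows <= exact_threshold`` the exhaustive optimum is returned.
    Ties break toward the identity-most ordering (the exhaustive solver
    scans permutations in lexicographic order; the heuristic compares
    against the identity path).
    """
    matrix = np.asarray(matrix)
    if matrix.size == 0 or matrix.shape[0] == 0:
        raise ValueError("cannot seriate an empty matrix")
    n = matrix.shape[0]
    if n == 1:
        return np.array([0])
    dist = cosine_distance_matrix(matrix)
    if n <= exact_threshold:
        best = _exhaustive_path(dist)
        identity = np.arange(n)
        if np.isclose(_path_cost(identity, dist), _path_cost(best, dist)):
            return identity
        return best
    best, best_cost = None, np.inf
    for start in range(n):
        order = _two_opt(_nearest_neighbor_path(dist, start), dist)
        cost = _path_cost(order, dist)
        if cost < best_cost - 1e-12:
            best, best_cost = order, cost
    identity = np.arange(n)
    if np.isclose(_path_cost(identity, dist), best_cost):
        return identity
    return best


def seriation_path_cost(matrix: np.ndarray, order: np.ndarray) -> float:
    return _path_cost(np.asarray(order), cosine_distance_matrix(matrix))


# ---------------------------------------------------------------------------
# cross-population matching
# ---------------------------------------------------------------------------


def match_populations(blocks: list[np.ndarray]) -> list[np.ndarray]:
    """Seriate the first block; align the second to it by optimal assignment.

    Returns the row orders (permutations) for the two blocks.  With unequal
    row counts, min(count) rows of the larger direction are assigned and the
    remainder is appended in seriated order.
    """
    if len(blocks) != 2:
        raise ValueError("match_populations expects exactly 2 population blocks")
    a, b = (np.asarray(x) for x in blocks)
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"column mismatch: {a.shape[1]} vs {b.shape[1]}")
    order_a = seriate_rows(a)
    cross = cdist(a[order_a].astype(float), b.astype(float), metric="cosine")
    cross = np.nan_to_num(cross, nan=1.0)
    n_assign = min(a.shape[0], b.shape[0])
    rows, cols = linear_sum_assignment(cross[:n_assign])
    order_b = np.full(b.shape[0], -1)
    # row i of the seriated first block gets partner cols[rows == i]
    assigned = cols[np.argsort(rows)]
    order_b[: len(assigned)] = assigned
    leftover = np.setdiff1d(np.arange(b.shape[0]), assigned)
    if len(leftover):
        sub_order = seriate_rows(b[leftover])
        order_b[len(assigned) :] = leftover[sub_order]
    return [order_a, order_b]


def matching_cost(blocks: list[np.ndarray], orders: list[np.ndarray]) -> float:
    """Total cosine distance of matched row pairs under the given orders."""
    a, b = (np.asarray(x) for x in blocks)
    order_a, order_b = orders
    n = min(len(order_a), len(order_b))
    d = cdist(a[order_a[:n]].astype(float), b[order_b[:n]].astype(float), metric="cosine")
    d = np.nan_to_num(d, nan=1.0)
    return float(np.diag(d).sum())


def build_padded_alignment(
    genotype_blocks: list[np.ndarray], width: int, match: bool = True
) -> PaddedAlignment:
    """Seriation (+ assignment) then zero-padding, one channel per block."""
    blocks = [np.asarray(x) for x in genotype_blocks]
    if len(blocks) == 2 and match:
        orders = match_populations(blocks)
        blocks = [blocks[0][orders[0]], blocks[1][orders[1]]]
    else:
        blocks = [b[seriate_rows(b)] for b in blocks]
    padded = [pad_or_crop(b, width) for b in blocks]
    return PaddedAlignment(np.stack(padded, axis=0))


# ---------------------------------------------------------------------------
# ResNet34-shape parameter accounting
# ---------------------------------------------------------------------------


def _resnet34_layer_counts(input_channels: int, output_size: int) -> dict[str, int]:
    """Exact per-layer learnable-scalar counts of the ResNet34 shape.

    Stem conv 7x7 (no bias) + batch norm; four stages of basic blocks
    ([3, 4, 6, 3] blocks at widths [64, 128, 256, 512]), each block two 3x3
    convolutions with batch norms and a 1x1 projection (with batch norm)
    wherever the width changes; global pooling; final affine classifier.
    Batch norms contribute weight + bias (2 per channel).
    """
    counts: dict[str, int] = {}
    counts["conv1"] = input_channels * 64 * 7 * 7
    counts["bn1"] = 2 * 64
    widths = [64, 128, 256, 512]
    blocks = [3, 4, 6, 3]
    in_ch = 64
    for stage, (w, n_blocks) in enumerate(zip(widths, blocks), start=1):
        for b in range(n_blocks):
            prefix = f"layer{stage}.{b}"
            counts[f"{prefix}.conv1"] = in_ch * w * 9
            counts[f"{prefix}.bn1"] = 2 * w
            counts[f"{prefix}.conv2"] = w * w * 9
            counts[f"{prefix}.bn2"] = 2 * w
            if in_ch != w:
                counts[f"{prefix}.downsample.conv"] = in_ch * w
                counts[f"{prefix}.downsample.bn"] = 2 * w
            in_ch = w
    counts["fc"] = 512 * output_size + output_size
    return counts


def baseline_param_count(config: BaselineNetConfig, itemized: bool = False):
    """Total learnable parameters of the baseline network shape."""
    if config.architecture != "resnet34-shape":
        raise ValueError(f"unknown baseline architecture {config.architecture!r}")
    counts = _resnet34_layer_counts(config.input_channels, config.output_size)
    total = sum(counts.values())
    if itemized:
        return total, counts
    return total
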