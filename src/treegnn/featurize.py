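"""Convert tree-sequence records into graph-learning inputs.

Per marginal tree the network consumes a node feature matrix (normalized
log-age, normalized branch mutation count, and a one-hot role block over
{internal, pop_1, ..., pop_k}, so F = 2 + k + 1), a child->parent edge
index, and a 12-dimensional tree summary vector; per sequence it consumes a
37-dimensional global summary (elementwise mean/sd/median of the tree
summaries plus the original tree count).  Normalization statistics are
fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .treeseq import MarginalTree, TreeSequenceRecord

TREE_SUMMARY_DIM = 12
GLOBAL_SUMMARY_DIM = 3 * TREE_SUMMARY_DIM + 1  # 37
DEFAULT_TREE_CAP = 128

SCHEMA_VERSION = 1


class NormalizationError(RuntimeError):
    pass


@dataclass
class NormalizationStats:
    """Training-split means/sds for every normalized channel.

    ``log_age`` pools internal nodes only (leaf slots are a post-normalization
    constant 0); ``mutations`` pools all nodes, root included.
    Degenerate sds (< 1e-12) are replaced by 1 so constant channels map to 0.
    """

    log_age_mean: float = 0.0
    log_age_sd: float = 1.0
    mutations_mean: float = 0.0
    mutations_sd: float = 1.0
    tree_summary_mean: np.ndarray | None = None
    tree_summary_sd: np.ndarray | None = None
    global_summary_mean: np.ndarray | None = None
    global_summary_sd: np.ndarray | None = None
    target_mean: np.ndarray | None = None
    target_sd: np.ndarray | None = None
    fitted: bool = False
    degenerate_dims: list = field(default_factory=list)

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "log_age_mean": self.log_age_mean,
                "log_age_sd": self.log_age_sd,
                "mutations_mean": self.mutations_mean,
                "mutations_sd": self.mutations_sd,
                "tree_summary_mean": arr(self.tree_summary_mean),
                "tree_summary_sd": arr(self.tree_summary_sd),
                "global_summary_mean": arr(self.global_summary_mean),
                "global_summary_sd": arr(self.global_summary_sd),
                "target_mean": arr(self.target_mean),
                "target_sd": arr(self.target_sd),
                "fitted": self.fitted,
                "degenerate_dims": self.degenerate_dims,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise NormalizationError("unknown normalization schema version")

        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            log_age_mean=d["log_age_mean"],
            log_age_sd=d["log_age_sd"],
            mutations_mean=d["mutations_mean"],
            mutations_sd=d["mutations_sd"],
            tree_summary_mean=arr(d["tree_summary_mean"]),
            tree_summary_sd=arr(d["tree_summary_sd"]),
            global_summary_mean=arr(d["global_summary_mean"]),
            global_summary_sd=arr(d["global_summary_sd"]),
            target_mean=arr(d["target_mean"]),
            target_sd=arr(d["target_sd"]),
            fitted=d["fitted"],
            degenerate_dims=d.get("degenerate_dims", []),
        )


def n_node_features(k_populations: int) -> int:
    """F = 2 + (k + 1): log-age, mutation count, one-hot role block."""
    return 2 + k_populations + 1


# ---------------------------------------------------------------------------
# per-tree featurization
# ---------------------------------------------------------------------------


def node_ordering(tree: MarginalTree) -> list[int]:
    """Leaves first (in sample order), then internal nodes by ascending time."""
    leaves = sorted((v for v in tree.nodes if v.is_leaf), key=lambda v: v.id)
    internal = sorted((v for v in tree.nodes if not v.is_leaf), key=lambda v: (v.time, v.id))
    return [v.id for v in leaves] + [v.id for v in internal]


def _raw_node_columns(tree: MarginalTree, k: int, order: list[int] | None = None):
    if order is None:
        order = node_ordering(tree)
    by_id = {v.id: v for v in tree.nodes}
    n_nodes = len(order)
    log_age = np.zeros(n_nodes)
    mutations = np.zeros(n_nodes)
    onehot = np.zeros((n_nodes, k + 1))
    for row, nid in enumerate(order):
        v = by_id[nid]
        mutations[row] = v.mutations_above
        if v.is_leaf:
            onehot[row, 1 + v.population] = 1.0
        else:
            log_age[row] = np.log(v.time)
            onehot[row, 0] = 1.0
    is_leaf = onehot[:, 0] == 0.0
    return log_age, mutations, onehot, is_leaf


def build_node_features(
    tree: MarginalTree, stats: NormalizationStats, k_populations: int
) -> np.ndarray:
    """(2n-1) x F feature matrix in node_ordering row order.

    Column 0 is the standardized log-age for internal nodes and exactly 0
    for leaves (a post-normalization constant); column 1 the standardized
    branch mutation count; the rest the one-hot role block.
    """
    if not stats.fitted:
        raise NormalizationError("normalization stats not fitted")
    log_age, mutations, onehot, is_leaf = _raw_node_columns(tree, k_populations)
    col0 = (log_age - stats.log_age_mean) / stats.log_age_sd
    col0[is_leaf] = 0.0
    col1 = (mutations - stats.mutations_mean) / stats.mutations_sd
    return np.column_stack([col0, col1, onehot])


def build_edge_index(tree: MarginalTree) -> np.ndarray:
    """2 x E array of (child_row, parent_row) pairs, child-to-parent directed."""
    order = node_ordering(tree)
    row_of = {nid: i for i, nid in enumerate(order)}
    pairs = sorted((row_of[c], row_of[p]) for c, p in tree.parent_of.items())
    return np.asarray(pairs, dtype=np.int64).T.reshape(2, -1)


def _median(x: np.ndarray) -> float:
    return float(np.median(x))


def tree_summary(tree: MarginalTree, sequence_length: float) -> np.ndarray:
    """The 12 hand-crafted per-tree statistics.

    Order: [TMRCA, mean/median/sd of coalescence times, mean/median/sd/skew/
    max of branch lengths, interval midpoint scaled to (0,1), span fraction,
    total branch length].  Moments use population (ddof=0) normalization and
    the Fisher-Pearson g1 skew (0 where the variance vanishes).
    """
    by_id = {v.id: v for v in tree.nodes}
    coal_times = np.array([v.time for v in tree.nodes if not v.is_leaf])
    branch_lengths = np.array(
        [by_id[p].time - by_id[c].time for c, p in tree.parent_of.items()]
    )
    m2 = float(np.mean((branch_lengths - branch_lengths.mean()) ** 2))
    if m2 > 0:
        m3 = float(np.mean((branch_lengths - branch_lengths.mean()) ** 3))
        skew = m3 / m2**1.5
    else:
        skew = 0.0
    left, right = tree.interval
    return np.array(
        [
            float(coal_times.max()),
            float(coal_times.mean()),
            _median(coal_times),
            float(coal_times.std()),
            float(branch_lengths.mean()),
            _median(branch_lengths),
            float(branch_lengths.std()),
            skew,
            float(branch_lengths.max()),
            (left + right) / (2.0 * sequence_length),
            (right - left) / sequence_length,
            float(branch_lengths.sum()),
        ]
    )


def sequence_summary(vectors: Sequence[np.ndarray], original_num_trees: int) -> np.ndarray:
    """37 values: columnwise mean(12), sd(12), median(12), original tree count."""
    if len(vectors) == 0:
        raise ValueError("sequence_summary requires at least one tree summary vector")
    stacked = np.asarray(vectors, dtype=float)
    if stacked.shape[1] != TREE_SUMMARY_DIM:
        raise ValueError(f"tree summary vectors must have {TREE_SUMMARY_DIM} dims")
    return np.concatenate(
        [
            stacked.mean(axis=0),
            stacked.std(axis=0),
            np.median(stacked, axis=0),
            [float(original_num_trees)],
        ]
    )


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


def downsample(
    record: TreeSequenceRecord,
    cap: int = DEFAULT_TREE_CAP,
    mode: str = "window",
    rng: np.random.Generator | None = None,
) -> TreeSequenceRecord:
    """Cap the number of trees in a record, remembering the original count.

    ``window`` keeps a contiguous run of ``cap`` trees with a uniform start;
    ``span_weighted`` draws ``cap`` trees with replacement with probability
    proportional to genomic span, then restores original order (duplicates
    retained).  Records at or under the cap pass through unchanged.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    T = record.num_trees
    if T <= cap:
        return record
    if rng is None:
        raise ValueError("downsampling requires a seeded rng")
    if mode == "window":
        start = int(rng.integers(0, T - cap + 1))
        kept = record.trees[start : start + cap]
    elif mode == "span_weighted":
        spans = np.array([t.span for t in record.trees], dtype=float)
        probs = spans / spans.sum()
        draws = np.sort(rng.choice(T, size=cap, replace=True, p=probs))
        kept = [record.trees[i] for i in draws]
    else:
        raise ValueError(f"unknown downsampling mode {mode!r}")
    return TreeSequenceRecord(
        trees=list(kept),
        sequence_length=record.sequence_length,
        n_samples=record.n_samples,
        k_populations=record.k_populations,
        provenance=record.provenance,
        label=record.label,
        original_num_trees=record.original_num_trees,
    )


# ---------------------------------------------------------------------------
# whole-record featurization
# ---------------------------------------------------------------------------


@dataclass
class FeaturizedSequence:
    """Network-ready arrays for one tree sequence."""

    node_features: list[np.ndarray]  # per tree: (2n-1, F)
    edge_indices: list[np.ndarray]  # per tree: (2, 2n-2)
    tree_summaries: np.ndarray  # (T, 12), normalized
    global_summary: np.ndarray  # (37,), normalized
    label: np.ndarray | None

    @property
    def num_trees(self) -> int:
        return len(self.node_features)


@dataclass
class RawSequenceFeatures:
    """Pre-normalization arrays for one (already downsampled) sequence.

    The streaming pipeline featurizes each simulated replicate immediately
    and discards the tree objects; normalization statistics are fitted over
    these raw arrays for the training split afterward.
    """

    log_ages: np.ndarray  # (T, 2n-1); 0 in leaf slots
    is_leaf: np.ndarray  # (2n-1,) bool; identical across trees of a task
    mutations: np.ndarray  # (T, 2n-1)
    onehots: np.ndarray  # (T, 2n-1, k+1)
    edge_indices: np.ndarray  # (T, 2, 2n-2)
    tree_summaries: np.ndarray  # raw (T, 12)
    global_summary: np.ndarray  # raw (37,)
    label: np.ndarray | None

    @property
    def num_trees(self) -> int:
        return self.log_ages.shape[0]


def raw_features(
    record: TreeSequenceRecord,
    cap: int | None = None,
    mode: str = "window",
    rng: np.random.Generator | None = None,
) -> RawSequenceFeatures:
    """Downsample (optionally) and extract raw feature arrays for one record."""
    if cap is not None:
        record = downsample(record, cap=cap, mode=mode, rng=rng)
    k = record.k_populations
    log_ages, mutations, onehots, edges = [], [], [], []
    is_leaf_ref = None
    for tree in record.trees:
        la, mu, oh, is_leaf = _raw_node_columns(tree, k)
        log_ages.append(la)
        mutations.append(mu)
        onehots.append(oh)
        edges.append(build_edge_index(tree))
        if is_leaf_ref is None:
            is_leaf_ref = is_leaf
    tv, gv = raw_summaries(record)
    label = record.label
    if label is not None:
        label = np.atleast_1d(np.asarray(label, dtype=float))
    return RawSequenceFeatures(
        log_ages=np.asarray(log_ages),
        is_leaf=np.asarray(is_leaf_ref),
        mutations=np.asarray(mutations),
        onehots=np.asarray(onehots),
        edge_indices=np.asarray(edges),
        tree_summaries=tv,
        global_summary=gv,
        label=label,
    )


def fit_normalization_raw(raws: Sequence[RawSequenceFeatures]) -> NormalizationStats:
    """Fit channel statistics over raw feature arrays (training split only)."""
    if len(raws) == 0:
        raise NormalizationError("cannot fit normalization on an empty training pool")
    stats = NormalizationStats(fitted=True)
    la = np.concatenate([r.log_ages[:, ~r.is_leaf].ravel() for r in raws])
    mu = np.concatenate([r.mutations.ravel() for r in raws])
    tv = np.concatenate([r.tree_summaries for r in raws], axis=0)
    gv = np.stack([r.global_summary for r in raws])

    def guarded(sd, name):
        sd = np.atleast_1d(np.asarray(sd, dtype=float))
        bad = sd < 1e-12
        if bad.any():
            stats.degenerate_dims.append(name)
            sd = np.where(bad, 1.0, sd)
        return sd

    stats.log_age_mean = float(la.mean())
    stats.log_age_sd = float(guarded(la.std(), "log_age")[0])
    stats.mutations_mean = float(mu.mean())
    stats.mutations_sd = float(guarded(mu.std(), "mutations")[0])
    stats.tree_summary_mean = tv.mean(axis=0)
    stats.tree_summary_sd = guarded(tv.std(axis=0), "tree_summary")
    stats.global_summary_mean = gv.mean(axis=0)
    stats.global_summary_sd = guarded(gv.std(axis=0), "global_summary")
    return stats


def normalize_raw(raw: RawSequenceFeatures, stats: NormalizationStats) -> FeaturizedSequence:
    """Apply fitted statistics to raw arrays, producing network inputs."""
    if not stats.fitted:
        raise NormalizationError("normalization stats not fitted")
    T = raw.num_trees
    col0 = (raw.log_ages - stats.log_age_mean) / stats.log_age_sd
    col0[:, raw.is_leaf] = 0.0
    col1 = (raw.mutations - stats.mutations_mean) / stats.mutations_sd
    node_features = [
        np.column_stack([col0[t], col1[t], raw.onehots[t]]) for t in range(T)
    ]
    tv = (raw.tree_summaries - stats.tree_summary_mean) / stats.tree_summary_sd
    gv = (raw.global_summary - stats.global_summary_mean) / stats.global_summary_sd
    return FeaturizedSequence(
        node_features=node_features,
        edge_indices=[raw.edge_indices[t] for t in range(T)],
        tree_summaries=tv,
        global_summary=gv,
        label=raw.label,
    )


def raw_summaries(record: TreeSequenceRecord) -> tuple[np.ndarray, np.ndarray]:
    """Un-normalized (T, 12) tree summaries and (37,) global summary."""
    vectors = [tree_summary(t, record.sequence_length) for t in record.trees]
    global_vec = sequence_summary(vectors, record.original_num_trees)
    return np.asarray(vectors), global_vec


def fit_normalization(records: Iterable[TreeSequenceRecord]) -> NormalizationStats:
    """Fit all feature-channel statistics on the training split only."""
    log_ages: list[np.ndarray] = []
    mut_counts: list[np.ndarray] = []
    tree_vecs: list[np.ndarray] = []
    global_vecs: list[np.ndarray] = []
    count = 0
    for record in records:
        count += 1
        for tree in record.trees:
            la, mu, onehot, is_leaf = _raw_node_columns(tree, record.k_populations)
            log_ages.append(la[~is_leaf])
            mut_counts.append(mu)
        tv, gv = raw_summaries(record)
        tree_vecs.append(tv)
        global_vecs.append(gv)
    if count == 0:
        raise NormalizationError("cannot fit normalization on an empty training pool")
    stats = NormalizationStats(fitted=True)
    la = np.concatenate(log_ages)
    mu = np.concatenate(mut_counts)
    tv = np.concatenate(tree_vecs, axis=0)
    gv = np.asarray(global_vecs)

    def guarded(sd, name):
        sd = np.atleast_1d(np.asarray(sd, dtype=float))
        bad = sd < 1e-12
        if bad.any():
            stats.degenerate_dims.append(name)
            sd = np.where(bad, 1.0, sd)
        return sd

    stats.log_age_mean = float(la.mean())
    stats.log_age_sd = float(guarded(la.std(), "log_age")[0])
    stats.mutations_mean = float(mu.mean())
    stats.mutations_sd = float(guarded(mu.std(), "mutations")[0])
    stats.tree_summary_mean = tv.mean(axis=0)
    stats.tree_summary_sd = guarded(tv.std(axis=0), "tree_summary")
    stats.global_summary_mean = gv.mean(axis=0)
    stats.global_summary_sd = guarded(gv.std(axis=0), "global_summary")
    return stats


def apply_normalization(record: TreeSequenceRecord, stats: NormalizationStats) -> FeaturizedSequence:
    """Featurize one record with previously fitted statistics."""
    if not stats.fitted:
        raise NormalizationError("normalization stats not fitted")
    k = record.k_populations
    node_features = [build_node_features(t, stats, k) for t in record.trees]
    edge_indices = [build_edge_index(t) for t in record.trees]
    tv, gv = raw_summaries(record)
    tv = (tv - stats.tree_summary_mean) / stats.tree_summary_sd
    gv = (gv - stats.global_summary_mean) / stats.global_summary_sd
    label = record.label
    if label is not None:
        label = np.atleast_1d(np.asarray(label, dtype=float))
    return FeaturizedSequence(
        node_features=node_features,
        edge_indices=edge_indices,
        tree_summaries=tv,
        global_summary=gv,
        label=label,
    )


def featurize_records(
    records: Sequence[TreeSequenceRecord],
    stats: NormalizationStats,
    cap: int = DEFAULT_TREE_CAP,
    mode: str = "window",
    rng: np.random.Generator | None = None,
) -> list[FeaturizedSequence]:
    return [apply_normalization(downsample(r, cap=cap, mode=mode, rng=rng), stats) for r in records]


# ---------------------------------------------------------------------------
# feature archives (one hierarchical container per dataset split)
# ---------------------------------------------------------------------------


def save_archive(path, sequences: Sequence[FeaturizedSequence], stats: NormalizationStats) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["normalization"] = stats.to_json()
        for i, seq in enumerate(sequences):
            g = f.create_group(f"seq{i:06d}")
            g.create_dataset("tree_summaries", data=seq.tree_summaries)
            g.create_dataset("global_summary", data=seq.global_summary)
            if seq.label is not None:
                g.create_dataset("label", data=seq.label)
            for j, (nf, ei) in enumerate(zip(seq.node_features, seq.edge_indices)):
                g.create_dataset(f"node_features/{j:05d}", data=nf.astype(np.float32))
                g.create_dataset(f"edge_index/{j:05d}", data=ei.astype(np.int32))


def save_raw_archive(path, raws: Sequence[RawSequenceFeatures]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for i, raw in enumerate(raws):
            g = f.create_group(f"seq{i:06d}")
            g.create_dataset("log_ages", data=raw.log_ages.astype(np.float32))
            g.create_dataset("is_leaf", data=raw.is_leaf)
            g.create_dataset("mutations", data=raw.mutations.astype(np.float32))
            g.create_dataset("onehots", data=raw.onehots.astype(np.int8))
            g.create_dataset("edge_indices", data=raw.edge_indices.astype(np.int32))
            g.create_dataset("tree_summaries", data=raw.tree_summaries)
            g.create_dataset("global_summary", data=raw.global_summary)
            if raw.label is not None:
                g.create_dataset("label", data=raw.label)


def load_raw_archive(path) -> list[RawSequenceFeatures]:
    import h5py

    raws = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            raws.append(
                RawSequenceFeatures(
                    log_ages=g["log_ages"][...].astype(float),
                    is_leaf=g["is_leaf"][...].astype(bool),
                    mutations=g["mutations"][...].astype(float),
                    onehots=g["onehots"][...].astype(float),
                    edge_indices=g["edge_indices"][...].astype(np.int64),
                    tree_summaries=g["tree_summaries"][...],
                    global_summary=g["global_summary"][...],
                    label=g["label"][...] if "label" in g else None,
                )
            )
    return raws


def load_archive(path) -> tuple[list[FeaturizedSequence], NormalizationStats]:
    import h5py

    sequences = []
    with h5py.File(path, "r") as f:
        stats = NormalizationStats.from_json(f.attrs["normalization"])
        for key in sorted(f.keys()):
            g = f[key]
            tree_keys = sorted(g["node_features"].keys())
            sequences.append(
                FeaturizedSequence(
                    node_features=[g[f"node_features/{k}"][...].astype(float) for k in tree_keys],
                    edge_indices=[g[f"edge_index/{k}"][...].astype(np.int64) for k in tree_keys],
                    tree_summaries=g["tree_summaries"][...],
                    global_summary=g["global_summary"][...],
                    label=g["label"][...] if "label" in g else None,
                )
            )
    return sequences, stats
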