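"""End-to-end dataset assembly and task training glue.

Streams simulation replicates straight into raw feature arrays (tree
objects are discarded per replicate), fits normalization and target
statistics on the training split only, and returns network-ready splits.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .featurize import (
    FeaturizedSequence,
    NormalizationStats,
    RawSequenceFeatures,
    fit_normalization_raw,
    n_node_features,
    normalize_raw,
    raw_features,
)
from .nn.model import ArchitectureConfig, LossSpec, TreeSequenceNet
from .simulate import (
    DemogTaskConfig,
    IntrogTaskConfig,
    RecombTaskConfig,
    iter_demography,
    iter_introgression,
    iter_recombination,
)
from .train import TargetStats, TrainConfig, standardize_targets

TASKS = ("recombination", "demography", "introgression", "sweeps")

_TASK_ITER = {
    "recombination": (iter_recombination, RecombTaskConfig),
    "demography": (iter_demography, DemogTaskConfig),
    "introgression": (iter_introgression, IntrogTaskConfig),
}

#: downsampling mode per task: contiguous windows except for sweeps, whose
#: selected site can sit anywhere along the locus
TASK_DOWNSAMPLE_MODE = {
    "recombination": "window",
    "demography": "window",
    "introgression": "window",
    "sweeps": "span_weighted",
}

TASK_KIND = {
    "recombination": "regression",
    "demography": "regression",
    "introgression": "classification",
    "sweeps": "classification",
}

TASK_OUTPUT_SIZE = {
    "recombination": 1,
    "demography": 5,
    "introgression": 3,
    "sweeps": 5,
}


@dataclass
class TaskDataset:
    """Raw (pre-normalization) features and targets for one task."""

    task: str
    raws: list[RawSequenceFeatures]
    targets: np.ndarray
    params: list[dict] = field(default_factory=list)
    k_populations: int = 1


def simulate_task_dataset(
    task: str,
    n_reps: int,
    seed: int,
    sim_config=None,
    tree_cap: int | None = 128,
) -> TaskDataset:
    """Simulate and featurize a task dataset replicate-by-replicate.

    The downsampling cap is applied inside record construction, so peak
    memory is one replicate's tree objects.  Mode follows the task's
    declared downsampling scheme.
    """
    if task not in _TASK_ITER:
        raise ValueError(f"cannot simulate task {task!r} (sweeps are ingested, not simulated)")
    iterator, default_config = _TASK_ITER[task]
    sim_config = sim_config or default_config()
    rng = np.random.default_rng(seed)
    raws, targets, params = [], [], []
    k_pop = 1
    gc_was = gc.isenabled()
    gc.disable()
    try:
        for record, _genotypes, target, p in iterator(
            n_reps, sim_config, rng=rng, base_seed=seed, max_trees=tree_cap
        ):
            k_pop = record.k_populations
            raws.append(raw_features(record))
            targets.append(target)
            params.append(p)
    finally:
        if gc_was:
            gc.enable()
            gc.collect()
    return TaskDataset(task, raws, np.asarray(targets), params, k_populations=k_pop)


@dataclass
class PreparedSplits:
    train: list[FeaturizedSequence]
    validation: list[FeaturizedSequence]
    test: list[FeaturizedSequence]
    stats: NormalizationStats
    target_stats: TargetStats | None
    n_node_features: int


def prepare_splits(
    dataset: TaskDataset,
    n_train: int,
    n_validation: int,
    n_test: int = 0,
    log_scale_targets: bool | None = None,
) -> PreparedSplits:
    """Split, fit statistics on the training portion only, and normalize.

    Regression targets are log-scaled then z-scored with training-split
    statistics (the task defaults: recombination and demography targets are
    strictly positive rates/sizes/times).
    """
    total = n_train + n_validation + n_test
    if total > len(dataset.raws):
        raise ValueError(f"requested {total} examples, dataset has {len(dataset.raws)}")
    kind = TASK_KIND[dataset.task]
    if log_scale_targets is None:
        log_scale_targets = kind == "regression" and dataset.task != "recombination"
    raws = dataset.raws
    stats = fit_normalization_raw(raws[:n_train])
    target_stats = None
    if kind == "regression":
        train_targets = dataset.targets[:n_train]
        if dataset.task == "recombination":
            # the simulator's target is already log r; standardize linearly
            target_stats = TargetStats.fit(train_targets.reshape(n_train, -1), log_scale=False)
        else:
            target_stats = TargetStats.fit(train_targets.reshape(n_train, -1), log_scale=log_scale_targets)

    def prepared(lo, hi):
        out = []
        for raw, target in zip(raws[lo:hi], dataset.targets[lo:hi]):
            seq = normalize_raw(raw, stats)
            if kind == "regression":
                seq.label = np.atleast_1d(
                    standardize_targets(np.atleast_1d(target), target_stats)
                )
            else:
                seq.label = np.atleast_1d(float(target))
            out.append(seq)
        return out

    return PreparedSplits(
        train=prepared(0, n_train),
        validation=prepared(n_train, n_train + n_validation),
        test=prepared(n_train + n_validation, total),
        stats=stats,
        target_stats=target_stats,
        n_node_features=n_node_features(dataset.k_populations),
    )


def default_architecture(task: str, k_populations: int, **overrides) -> ArchitectureConfig:
    cfg = ArchitectureConfig(
        n_node_features=n_node_features(k_populations),
        output_size=TASK_OUTPUT_SIZE[task],
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


#: per-task training defaults: the GCN batch sizes and optimizer settings
TASK_TRAIN_DEFAULTS = {
    "recombination": dict(batch_size=16, loss=LossSpec("smooth_l1"), classification=False),
    "demography": dict(batch_size=30, loss=LossSpec("smooth_l1"), classification=False),
    "introgression": dict(batch_size=36, loss=LossSpec("categorical_cross_entropy"), classification=True),
    "sweeps": dict(batch_size=20, loss=LossSpec("categorical_cross_entropy"), classification=True),
}


def default_train_config(task: str, **overrides) -> TrainConfig:
    kwargs = dict(TASK_TRAIN_DEFAULTS[task])
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
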