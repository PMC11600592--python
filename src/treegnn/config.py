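"""Run configuration schema, serialization, and provenance manifests.

Configs are plain YAML/JSON mappings validated against a dataclass schema:
unknown keys are rejected (with a close-match suggestion), defaults are
materialized explicitly on write, and a canonical hash ties every artifact
to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

STAGES = ("simulate", "infer-trees", "featurize", "train", "evaluate", "predict", "fixtures")


class ConfigError(ValueError):
    pass


@dataclass
class SimulateSection:
    n_reps: int = 100
    tree_cap: int = 128
    #: overrides forwarded to the task's simulation config dataclass
    sim_params: dict = field(default_factory=dict)


@dataclass
class FeaturizeSection:
    cap: int = 128
    mode: str = "window"


@dataclass
class ModelSection:
    node_embedding_width: int = 26
    n_conv_layers: int = 6
    tree_hidden: int = 256
    sequence_hidden: int = 256
    head_width: int = 128
    use_graph_conv: bool = True
    use_tree_summary: bool = True
    use_global_summary: bool = True


@dataclass
class TrainSection:
    learning_rate: float = 1e-5
    batch_size: int | None = None  # task default when unset
    max_epochs: int = 100
    patience: int = 10
    n_train: int = 64
    n_validation: int = 16
    n_test: int = 0


@dataclass
class RunConfig:
    task: str = "recombination"
    stage: str = "simulate"
    seed: int = 0
    out_dir: str = "runs"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    featurize: FeaturizeSection = field(default_factory=FeaturizeSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)

    def __post_init__(self):
        from .pipeline import TASKS

        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}; expected one of {STAGES}")


def _build_section(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            suggestion = difflib.get_close_matches(key, fields, n=1)
            hint = f"; did you mean {suggestion[0]!r}?" if suggestion else ""
            raise ConfigError(f"unknown key {path}{key!r}{hint}")
        f = fields[key]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[key] = _build_section(f.type, value, f"{path}{key}.")
        elif isinstance(value, dict) and f.name in ("simulate", "featurize", "model", "train"):
            section_cls = {
                "simulate": SimulateSection,
                "featurize": FeaturizeSection,
                "model": ModelSection,
                "train": TrainSection,
            }[f.name]
            kwargs[key] = _build_section(section_cls, value, f"{path}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def parse_config(data: dict) -> RunConfig:
    """Validate a plain mapping into a RunConfig, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return _build_section(RunConfig, data, "")


def load_config(path) -> RunConfig:
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return parse_config(data or {})


def dump_config(config: RunConfig) -> dict:
    """Materialize every field (defaults included) as a plain mapping."""
    return dataclasses.asdict(config)


def config_roundtrip(config: RunConfig) -> RunConfig:
    """serialize -> parse; structurally identical by construction."""
    return parse_config(json.loads(json.dumps(dump_config(config))))


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(dump_config(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(
    out_dir, config: RunConfig, artifacts: dict[str, str], parent: str | None = None
) -> Path:
    """Write the provenance manifest next to a stage's artifacts."""
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": config.stage,
        "task": config.task,
        "seed": config.seed,
        "config": dump_config(config),
        "config_hash": config_hash(config),
        "artifacts": artifacts,
        "parent_manifest": parent,
        "versions": {
            "treegnn": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
        "created": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / f"manifest_{config.stage}.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    tmp.replace(path)
    return path
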