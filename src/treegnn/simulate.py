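"""Coalescent benchmark-data generation, sweep-dataset ingestion, fixtures.

Four study conditions are emulated at configurable scale:

* recombination-rate regression: single panmictic population of size N drawn
  from {1000, 2000, 5000, 10000, 20000, 50000}, a 20 kb locus, mu = 1.5e-8,
  and a per-bp crossover rate r from a truncated exponential on
  [1e-8, 1e-6]; the target is log r.
* three-epoch demographic parameter regression (N0, T1, N1, T2, N2).
* two-population introgression classification (pulse admixture in either
  direction, or none; three balanced classes).
* five-class sweep classification: simulations of selection come from an
  external forward/coalescent selection simulator and are ingested from
  ms-style files plus a label manifest; they are not generated here.

Population sizes follow the diploid convention of the simulation backend
(`msprime` ``population_size``): the expected pairwise coalescence time
within a panmictic population of size N is 2N generations.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .treeseq import (
    GenotypeMatrix,
    MarginalTree,
    Node,
    TreeSequenceRecord,
    UNKNOWN_POPULATION,
    read_ms,
    record_from_tskit,
    validate_record,
)

_SEED_STRIDE = 2654435761  # Knuth multiplicative-hash stride


def replicate_seed(base_seed: int, index: int) -> int:
    """Counter-based per-replicate seed, always in [1, 2^31)."""
    return int((base_seed + (index + 1) * _SEED_STRIDE) % (2**31 - 1)) + 1


class ExternalToolError(RuntimeError):
    pass


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# task configurations
# ---------------------------------------------------------------------------


@dataclass
class RecombTaskConfig:
    population_sizes: tuple[int, ...] = (1000, 2000, 5000, 10000, 20000, 50000)
    sequence_length: float = 20_000.0
    mutation_rate: float = 1.5e-8
    r_lower: float = 1e-8
    r_upper: float = 1e-6
    r_mean: float = 1e-7  # pre-truncation exponential mean
    n_samples: int = 50
    #: multiplicative shift factors for the misspecification study
    rate_shift: float = 1.0


@dataclass
class DemogTaskConfig:
    n0_range: tuple[float, float] = (100.0, 4e4)
    t1_range: tuple[float, float] = (100.0, 3500.0)
    n1_range: tuple[float, float] = (100.0, 5000.0)
    dt2_range: tuple[float, float] = (1.0, 3500.0)  # T2 = T1 + U[dt2]
    n2_range: tuple[float, float] = (100.0, 2e4)
    sequence_length: float = 100_000.0
    mutation_rate: float = 1.5e-8
    recombination_rate: float = 1e-8
    n_samples: int = 50


@dataclass
class IntrogTaskConfig:
    """Generic two-population isolation-with-pulse-admixture model.

    The pulse occurs at t ~ U(0.3, 0.5) x T in one of the two directions,
    or not at all; the three classes are balanced.  Class labels: 0 = pulse
    from population 0 into population 1, 1 = pulse from 1 into 0, 2 = none.
    """

    split_time: float = 500_000.0  # T, generations
    pulse_time_range: tuple[float, float] = (0.3, 0.5)  # x T
    pulse_fraction: float = 0.2
    pop_sizes: tuple[float, float, float] = (1e5, 1e5, 1e5)  # pop0, pop1, ancestral
    samples: tuple[int, int] = (20, 14)
    sequence_length: float = 10_000.0
    mutation_rate: float = 5e-9
    recombination_rate: float = 1e-8


@dataclass
class SweepTaskSpec:
    classes: tuple[str, ...] = ("hard", "hard-linked", "soft", "soft-linked", "neutral")
    fixation_time_range: tuple[float, float] = (0.0, 2000.0)
    central_fraction: float = 1.0 / 11.0
    n_samples: int = 104


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    records: list[TreeSequenceRecord]
    genotypes: list[GenotypeMatrix]
    targets: np.ndarray
    params: list[dict] = field(default_factory=list)


def _collect(iterator) -> "SimulatedDataset":
    records, genotypes, targets, params = [], [], [], []
    for record, gm, target, p in iterator:
        records.append(record)
        genotypes.append(gm)
        targets.append(target)
        params.append(p)
    return SimulatedDataset(records, genotypes, np.asarray(targets), params)


def _truncated_exponential(rng: np.random.Generator, mean: float, lower: float, upper: float) -> float:
    """Inverse-CDF draw from Exp(mean) conditioned on [lower, upper]."""
    a = np.exp(-lower / mean)
    b = np.exp(-upper / mean)
    u = rng.uniform()
    return -mean * np.log(a - u * (a - b))


def _simulate_one(
    *,
    demography=None,
    population_size=None,
    samples,
    sequence_length,
    recombination_rate,
    mutation_rate,
    seed,
):
    import msprime

    try:
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            population_size=population_size,
            ploidy=2,
            sequence_length=sequence_length,
            recombination_rate=recombination_rate,
            random_seed=seed,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=seed + 1,
        )
    except Exception as exc:  # pragma: no cover - backend failure surface
        raise SimulationError(f"coalescent backend failed: {exc}") from exc
    return ts


def _genotypes_from_ts(ts) -> GenotypeMatrix:
    import tskit

    alleles = ts.genotype_matrix().T.astype(np.int8)
    positions = np.array([s.position for s in ts.sites()], dtype=float)
    pops = []
    for s in ts.samples():
        p = ts.node(s).population
        pops.append(0 if p in (-1, tskit.NULL) else int(p))
    return GenotypeMatrix(alleles, positions, np.asarray(pops))


# ---------------------------------------------------------------------------
# task simulators
# ---------------------------------------------------------------------------


def iter_recombination(
    n_reps: int,
    config: RecombTaskConfig | None = None,
    rng: np.random.Generator | None = None,
    base_seed: int | None = None,
    max_trees: int | None = None,
):
    """Yield (record, genotypes, target, params) per replicate (streaming).

    Each replicate carries the true marginal-tree sequence (provenance
    ``true_simulation``) and the binary genotype matrix; target = log r.
    ``max_trees`` optionally applies the window downsampling cap during
    record construction (``original_num_trees`` keeps the full count).
    """
    import msprime

    config = config or RecombTaskConfig()
    if rng is None:
        raise ValueError("a seeded rng is required")
    if base_seed is None:
        base_seed = int(rng.integers(1, 2**31 - 1))
    for i in range(n_reps):
        N = int(rng.choice(config.population_sizes))
        r = _truncated_exponential(
            rng,
            config.r_mean * config.rate_shift,
            config.r_lower,
            config.r_upper * config.rate_shift,
        )
        seed = replicate_seed(base_seed, i)
        ts = _simulate_one(
            samples=[msprime.SampleSet(config.n_samples, ploidy=1)],
            population_size=N,
            sequence_length=config.sequence_length,
            recombination_rate=r,
            mutation_rate=config.mutation_rate,
            seed=seed,
        )
        down_rng = np.random.default_rng(replicate_seed(base_seed, i) + 7)
        record = record_from_tskit(
            ts,
            provenance="true_simulation",
            label=np.log(r),
            max_trees=max_trees,
            rng=down_rng if max_trees else None,
        )
        yield record, _genotypes_from_ts(ts), np.log(r), {
            "N": N, "r": r, "rho": 4 * N * r * config.sequence_length, "seed": seed,
        }


def sim_recombination(n_reps, config=None, rng=None, base_seed=None, max_trees=None) -> SimulatedDataset:
    """Materialized recombination-task dataset (see iter_recombination)."""
    return _collect(iter_recombination(n_reps, config, rng, base_seed, max_trees))


def iter_demography(
    n_reps: int,
    config: DemogTaskConfig | None = None,
    rng: np.random.Generator | None = None,
    base_seed: int | None = None,
    max_trees: int | None = None,
):
    """Yield three-epoch replicates; target vector (N0, T1, N1, T2, N2), raw.

    Targets are log-scaled and standardized later (at target-stats fitting),
    not here.
    """
    import msprime

    config = config or DemogTaskConfig()
    if rng is None:
        raise ValueError("a seeded rng is required")
    if base_seed is None:
        base_seed = int(rng.integers(1, 2**31 - 1))
    for i in range(n_reps):
        N0 = rng.uniform(*config.n0_range)
        T1 = rng.uniform(*config.t1_range)
        N1 = rng.uniform(*config.n1_range)
        T2 = T1 + rng.uniform(*config.dt2_range)
        N2 = rng.uniform(*config.n2_range)
        demography = msprime.Demography()
        demography.add_population(name="pop", initial_size=N0)
        demography.add_population_parameters_change(time=T1, initial_size=N1)
        demography.add_population_parameters_change(time=T2, initial_size=N2)
        seed = replicate_seed(base_seed, i)
        ts = _simulate_one(
            samples=[msprime.SampleSet(config.n_samples, population="pop", ploidy=1)],
            demography=demography,
            sequence_length=config.sequence_length,
            recombination_rate=config.recombination_rate,
            mutation_rate=config.mutation_rate,
            seed=seed,
        )
        down_rng = np.random.default_rng(seed + 7)
        record = record_from_tskit(
            ts,
            provenance="true_simulation",
            label=np.array([N0, T1, N1, T2, N2]),
            max_trees=max_trees,
            rng=down_rng if max_trees else None,
        )
        yield record, _genotypes_from_ts(ts), np.array([N0, T1, N1, T2, N2]), {
            "N0": N0, "T1": T1, "N1": N1, "T2": T2, "N2": N2, "seed": seed,
        }


def sim_demography(n_reps, config=None, rng=None, base_seed=None, max_trees=None) -> SimulatedDataset:
    """Materialized demography-task dataset (see iter_demography)."""
    return _collect(iter_demography(n_reps, config, rng, base_seed, max_trees))


INTROG_CLASSES = ("pop0_to_pop1", "pop1_to_pop0", "none")


def iter_introgression(
    n_reps: int,
    config: IntrogTaskConfig | None = None,
    rng: np.random.Generator | None = None,
    base_seed: int | None = None,
    max_trees: int | None = None,
):
    """Yield balanced three-class introgression replicates (k = 2)."""
    import msprime

    config = config or IntrogTaskConfig()
    if rng is None:
        raise ValueError("a seeded rng is required")
    if base_seed is None:
        base_seed = int(rng.integers(1, 2**31 - 1))
    for i in range(n_reps):
        cls = i % 3  # balanced by construction (counts differ by <= 1)
        demography = msprime.Demography()
        demography.add_population(name="p0", initial_size=config.pop_sizes[0])
        demography.add_population(name="p1", initial_size=config.pop_sizes[1])
        demography.add_population(name="anc", initial_size=config.pop_sizes[2])
        pulse_time = None
        if cls != 2:
            lo, hi = config.pulse_time_range
            pulse_time = rng.uniform(lo, hi) * config.split_time
            # class 0: forward-time pulse from p0 into p1 => backwards in
            # time, lineages sampled in p1 migrate into p0
            source, dest = ("p1", "p0") if cls == 0 else ("p0", "p1")
            demography.add_mass_migration(
                time=pulse_time, source=source, dest=dest, proportion=config.pulse_fraction
            )
        else:
            rng.uniform()  # keep the draw stream aligned across classes
        demography.add_population_split(
            time=config.split_time, derived=["p0", "p1"], ancestral="anc"
        )
        demography.sort_events()
        seed = replicate_seed(base_seed, i)
        ts = _simulate_one(
            samples=[
                msprime.SampleSet(config.samples[0], population="p0", ploidy=1),
                msprime.SampleSet(config.samples[1], population="p1", ploidy=1),
            ],
            demography=demography,
            sequence_length=config.sequence_length,
            recombination_rate=config.recombination_rate,
            mutation_rate=config.mutation_rate,
            seed=seed,
        )
        down_rng = np.random.default_rng(seed + 7)
        record = record_from_tskit(
            ts,
            provenance="true_simulation",
            label=cls,
            max_trees=max_trees,
            rng=down_rng if max_trees else None,
        )
        yield record, _genotypes_from_ts(ts), cls, {
            "class": INTROG_CLASSES[cls],
            "pulse_time": pulse_time,
            "seed": seed,
            "migration_event": cls != 2,
        }


def sim_introgression(n_reps, config=None, rng=None, base_seed=None, max_trees=None) -> SimulatedDataset:
    """Materialized introgression-task dataset (see iter_introgression)."""
    return _collect(iter_introgression(n_reps, config, rng, base_seed, max_trees))


# ---------------------------------------------------------------------------
# sweep-task ingestion (simulations produced externally)
# ---------------------------------------------------------------------------


SWEEP_CLASS_INDEX = {name: i for i, name in enumerate(SweepTaskSpec().classes)}


@dataclass
class SweepDataset:
    genotypes: list[GenotypeMatrix]
    labels: np.ndarray  # class indices
    selected_positions: np.ndarray  # fractional positions; nan where none
    downsample_mode: str = "span_weighted"


def ingest_sweep_dataset(
    ms_text: str,
    manifest_rows: Sequence[tuple],
    spec: SweepTaskSpec | None = None,
    sequence_length: float = 1.0,
) -> SweepDataset:
    """Attach 5-class sweep labels to externally simulated ms replicates.

    ``manifest_rows``: (replicate_index, class_name, selected_position_fraction
    or None).  Labels are validated against the central-subwindow rule: a
    selected site inside the central 1/11 of the locus must carry a "sweep"
    class, one outside it a "linked" class.  Span-weighted downsampling is
    the declared mode for this task.
    """
    spec = spec or SweepTaskSpec()
    matrices = read_ms(ms_text, sequence_length)
    if len(manifest_rows) != len(matrices):
        raise ValueError(
            f"manifest has {len(manifest_rows)} rows for {len(matrices)} ms replicates"
        )
    labels = np.zeros(len(matrices), dtype=np.int64)
    positions = np.full(len(matrices), np.nan)
    seen = set()
    half = spec.central_fraction / 2.0
    for idx, cls_name, pos in manifest_rows:
        if cls_name not in SWEEP_CLASS_INDEX:
            raise ValueError(f"unknown sweep class {cls_name!r}")
        seen.add(cls_name)
        labels[idx] = SWEEP_CLASS_INDEX[cls_name]
        if pos is not None:
            pos = float(pos)
            positions[idx] = pos
            central = abs(pos - 0.5) <= half
            is_sweep = cls_name in ("hard", "soft")
            is_linked = cls_name in ("hard-linked", "soft-linked")
            if central and is_linked:
                raise ValueError(
                    f"replicate {idx}: selected site at {pos} is central but labeled {cls_name}"
                )
            if (not central) and is_sweep:
                raise ValueError(
                    f"replicate {idx}: selected site at {pos} is off-center but labeled {cls_name}"
                )
        elif cls_name != "neutral":
            raise ValueError(f"replicate {idx}: class {cls_name} requires a selected position")
    missing = set(spec.classes) - seen
    if missing:
        raise ValueError(f"manifest is missing classes: {sorted(missing)}")
    return SweepDataset(matrices, labels, positions)


# ---------------------------------------------------------------------------
# external genealogy-inference adapter
# ---------------------------------------------------------------------------


def infer_trees_adapter(
    genotypes: GenotypeMatrix,
    sequence_length: float,
    mean_mutation_rate: float,
    mean_recombination_rate: float,
    mean_population_size: float,
    tool: str = "Relate",
    workdir=None,
    log=None,
) -> TreeSequenceRecord:
    """Run an external genealogy-inference tool on one replicate.

    The tool is supplied the *means* of the simulated parameter
    distributions (its required point estimates).  Returns an ``inferred``
    record; raises ExternalToolError when the tool is not on PATH (there is
    deliberately no fallback to true trees).
    """
    import tempfile
    from pathlib import Path

    binary = shutil.which(tool)
    if binary is None:
        raise ExternalToolError(
            f"external tool unavailable: {tool!r} is not on PATH; "
            "install it or use true-simulation records"
        )
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="treegnn_infer_"))
    workdir.mkdir(parents=True, exist_ok=True)
    haps = workdir / "input.haps"
    sample = workdir / "input.sample"
    with open(haps, "w", encoding="utf-8") as fh:
        for j in range(genotypes.n_sites):
            alleles = "".join(f" {int(a)}" for a in genotypes.alleles[:, j])
            fh.write(f"1 snp{j} {int(genotypes.positions[j])} 0 1{alleles}\n")
    with open(sample, "w", encoding="utf-8") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for i in range(genotypes.n_rows):
            fh.write(f"s{i} s{i} 0\n")
    cmd = [
        binary,
        "--mode", "All",
        "-m", str(mean_mutation_rate),
        "-N", str(2 * mean_population_size),
        "--haps", str(haps),
        "--sample", str(sample),
        "--map", str(workdir / "input.map"),
        "-o", "inferred",
    ]
    with open(workdir / "input.map", "w", encoding="utf-8") as fh:
        fh.write("pos COMBINED_rate Genetic_Map\n")
        cm_per_mb = mean_recombination_rate * 1e8
        fh.write(f"0 {cm_per_mb} 0.0\n")
        fh.write(f"{int(sequence_length)} {cm_per_mb} {cm_per_mb * sequence_length / 1e6}\n")
    if log is not None:
        log(f"invoking {tool}: {' '.join(cmd)}")
    result = subprocess.run(cmd, cwd=workdir, capture_output=True, text=True)
    if result.returncode != 0:
        raise ExternalToolError(f"{tool} failed ({result.returncode}): {result.stderr[-500:]}")
    trees_path = workdir / "inferred.trees"
    if not trees_path.exists():
        # Relate emits .anc/.mut; its own converter produces the succinct format
        converter = shutil.which("RelateFileFormats")
        if converter is None:
            raise ExternalToolError(
                "RelateFileFormats converter unavailable to produce a .trees file"
            )
        conv = subprocess.run(
            [converter, "--mode", "ConvertToTreeSequence", "-i", "inferred", "-o", "inferred"],
            cwd=workdir, capture_output=True, text=True,
        )
        if conv.returncode != 0:
            raise ExternalToolError(f"conversion failed: {conv.stderr[-500:]}")
    import tskit

    record = record_from_tskit(tskit.load(trees_path), provenance="inferred")
    problems = validate_record(record)
    if problems:
        raise ExternalToolError("inferred record invalid: " + "; ".join(problems[:5]))
    return record


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------


def _two_leaf_record(internal_time: float = 10.0, L: float = 1000.0) -> TreeSequenceRecord:
    nodes = [
        Node(0, 0.0, True, 0, 1),
        Node(1, 0.0, True, 0, 2),
        Node(2, internal_time, False, UNKNOWN_POPULATION, 0),
    ]
    tree = MarginalTree(nodes=nodes, parent_of={0: 2, 1: 2}, interval=(0.0, L))
    return TreeSequenceRecord([tree], L, 2, 1, "true_simulation")


def _three_leaf_record(L: float = 1000.0) -> TreeSequenceRecord:
    # times {0,0,0,5,9}: ((0,1) at 5, then with 2 at 9)
    nodes = [
        Node(0, 0.0, True, 0, 0),
        Node(1, 0.0, True, 0, 1),
        Node(2, 0.0, True, 0, 3),
        Node(3, 5.0, False, UNKNOWN_POPULATION, 2),
        Node(4, 9.0, False, UNKNOWN_POPULATION, 0),
    ]
    tree = MarginalTree(nodes=nodes, parent_of={0: 3, 1: 3, 2: 4, 3: 4}, interval=(0.0, L))
    return TreeSequenceRecord([tree], L, 3, 1, "true_simulation")


def make_fixtures(seed: int = 0) -> dict[str, TreeSequenceRecord]:
    """Canned tiny records used across the test suites (deterministic)."""
    import msprime

    fixtures = {
        "twoLeaf10": _two_leaf_record(),
        "threeLeaf": _three_leaf_record(),
    }
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(8, ploidy=1)],
        population_size=1000,
        ploidy=2,
        sequence_length=5000,
        recombination_rate=5e-7,
        random_seed=seed + 11,
    )
    ts = msprime.sim_mutations(
        ts, rate=5e-7, model=msprime.BinaryMutationModel(), random_seed=seed + 12
    )
    fixtures["eightLeafSim"] = record_from_tskit(ts, provenance="true_simulation")
    return fixtures
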