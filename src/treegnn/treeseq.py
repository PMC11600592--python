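"""Data model and I/O for sequences of marginal genealogical trees.

A locus is represented as an ordered series of rooted binary trees, each
spanning a half-open genomic interval, the intervals tiling ``[0, L)``.
Coordinates are 0-based, half-open, in bp.  All leaves sit at time 0
(present-day sampling); internal node times are coalescence times in
generations.  Branch mutation counts live on the child node of each edge
(``mutations_above``).

Succinct tree-sequence files are read through :mod:`tskit`; a plain-text
dialect (one line per tree: left, right, Newick with branch lengths in
generations, plus an optional mutation-count companion table) is provided
for fixtures and interchange.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

UNKNOWN_POPULATION = -1

#: Exact parent/child time ties are forbidden (log-age features need strictly
#: positive, distinct internal times); loaders nudge offending nodes upward.
TIME_TIE_EPSILON = 1e-6


class TreeSequenceError(ValueError):
    """Raised on unloadable or structurally invalid tree-sequence input."""


class MsParseError(ValueError):
    """Raised on malformed ms-style simulator output, naming the line."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Node:
    id: int
    time: float
    is_leaf: bool
    population: int = UNKNOWN_POPULATION
    mutations_above: int = 0


@dataclass
class MarginalTree:
    """A rooted binary genealogy spanning ``[left, right)`` bp."""

    nodes: list[Node]
    parent_of: dict[int, int]
    interval: tuple[float, float]

    @property
    def n_leaves(self) -> int:
        return sum(1 for v in self.nodes if v.is_leaf)

    @property
    def root(self) -> Node:
        ids_with_parent = set(self.parent_of)
        roots = [v for v in self.nodes if v.id not in ids_with_parent]
        if len(roots) != 1:
            raise TreeSequenceError(f"expected a single root, found {len(roots)}")
        return roots[0]

    def node_by_id(self, node_id: int) -> Node:
        for v in self.nodes:
            if v.id == node_id:
                return v
        raise KeyError(node_id)

    def children_of(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for child, parent in self.parent_of.items():
            out.setdefault(parent, []).append(child)
        return out

    @property
    def span(self) -> float:
        return self.interval[1] - self.interval[0]


@dataclass
class TreeSequenceRecord:
    trees: list[MarginalTree]
    sequence_length: float
    n_samples: int
    k_populations: int = 1
    provenance: str = "true_simulation"
    label: np.ndarray | float | int | None = None
    #: tree count of the sequence before any downsampling was applied
    original_num_trees: int | None = None

    def __post_init__(self):
        if self.original_num_trees is None:
            self.original_num_trees = len(self.trees)

    @property
    def num_trees(self) -> int:
        return len(self.trees)


@dataclass
class GenotypeMatrix:
    """Binary haplotype alignment: rows = haploid genomes, cols = sites."""

    alleles: np.ndarray
    positions: np.ndarray
    population_of_row: np.ndarray | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions)
        if self.population_of_row is None:
            self.population_of_row = np.zeros(self.alleles.shape[0], dtype=np.int64)
        else:
            self.population_of_row = np.asarray(self.population_of_row, dtype=np.int64)

    @property
    def n_rows(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_record(record: TreeSequenceRecord) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the record is valid.  Violations name the tree index
    and the failed invariant rather than raising, so callers can report all
    defects of a file at once.
    """
    violations: list[str] = []
    if record.num_trees < 1:
        return ["record has no trees"]
    n = record.n_samples
    leaf_sets: list[frozenset[int]] = []
    for t, tree in enumerate(record.trees):
        left, right = tree.interval
        if not right > left:
            violations.append(f"tree {t}: empty interval [{left}, {right})")
        n_nodes = len(tree.nodes)
        n_leaves = tree.n_leaves
        if n_leaves != n:
            violations.append(
                f"tree {t}: {n_leaves} leaves, record declares n_samples={n}"
            )
        if n_nodes != 2 * n_leaves - 1:
            violations.append(
                f"tree {t}: non-binary: {n_nodes} nodes for {n_leaves} leaves"
            )
        if len(tree.parent_of) != n_nodes - 1:
            violations.append(
                f"tree {t}: {len(tree.parent_of)} edges, expected {n_nodes - 1}"
            )
        by_id = {v.id: v for v in tree.nodes}
        root_ids = [v.id for v in tree.nodes if v.id not in tree.parent_of]
        for child, parent in tree.parent_of.items():
            if child not in by_id or parent not in by_id:
                violations.append(f"tree {t}: edge ({child}->{parent}) references unknown node")
                continue
            if not by_id[parent].time > by_id[child].time:
                violations.append(
                    f"tree {t}: non-increasing time on edge {child}->{parent} "
                    f"({by_id[parent].time} <= {by_id[child].time})"
                )
        for v in tree.nodes:
            if v.is_leaf and v.time != 0:
                violations.append(f"tree {t}: leaf {v.id} has nonzero time {v.time}")
            if (not v.is_leaf) and v.time <= 0:
                violations.append(f"tree {t}: internal node {v.id} has non-positive time")
            if v.is_leaf and v.population == UNKNOWN_POPULATION:
                violations.append(f"tree {t}: leaf {v.id} has unknown population")
            if (not v.is_leaf) and v.population != UNKNOWN_POPULATION:
                violations.append(f"tree {t}: internal node {v.id} carries a population label")
            if v.is_leaf and not (0 <= v.population < record.k_populations):
                violations.append(
                    f"tree {t}: leaf {v.id} population {v.population} outside 0..{record.k_populations - 1}"
                )
            if v.mutations_above < 0:
                violations.append(f"tree {t}: node {v.id} negative mutation count")
        if len(root_ids) == 1 and by_id[root_ids[0]].mutations_above != 0:
            violations.append(f"tree {t}: root carries mutations_above != 0")
        leaf_sets.append(frozenset(v.id for v in tree.nodes if v.is_leaf))
    if len(set(leaf_sets)) > 1:
        violations.append("trees do not share a single leaf set")
    # interval tiling of [0, L)
    prev_right = 0.0
    for t, tree in enumerate(record.trees):
        left, right = tree.interval
        if not math.isclose(left, prev_right, rel_tol=0, abs_tol=1e-9):
            kind = "interval gap" if left > prev_right else "interval overlap"
            violations.append(f"tree {t}: {kind} at {prev_right} -> {left}")
        prev_right = right
    if not math.isclose(prev_right, record.sequence_length, rel_tol=0, abs_tol=1e-9):
        violations.append(
            f"tree {record.num_trees - 1}: intervals end at {prev_right}, "
            f"sequence_length is {record.sequence_length}"
        )
    return violations


def num_topology_breakpoints(record: TreeSequenceRecord) -> int:
    """Number of observable historical recombination events: T - 1.

    Computed on the original (pre-downsampling) tree count, because
    downsampling removes trees without removing the breakpoints they attest.
    """
    original = record.original_num_trees
    return (original if original is not None else record.num_trees) - 1


# ---------------------------------------------------------------------------
# ms-style simulator text
# ---------------------------------------------------------------------------


def read_ms(stream, sequence_length: float) -> list[GenotypeMatrix]:
    """Parse ms-dialect simulator output into one GenotypeMatrix per replicate.

    Replicates are delimited by ``//``; each carries ``segsites: s``, a
    ``positions:`` line of fractional coordinates, and one 0/1 row per
    haplotype.  Fractions are mapped to bp as ``floor(p * L)``; collisions are
    kept as distinct columns.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    matrices: list[GenotypeMatrix] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        # header: segsites
        while i < n_lines and not lines[i].strip():
            i += 1
        if i >= n_lines or not lines[i].strip().startswith("segsites:"):
            raise MsParseError("expected 'segsites: <int>' after '//'", i + 1)
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise MsParseError("unparseable segsites count", i + 1) from None
        i += 1
        if segsites == 0:
            matrices.append(
                GenotypeMatrix(np.zeros((0, 0), dtype=np.int8), np.zeros(0, dtype=np.int64))
            )
            continue
        while i < n_lines and not lines[i].strip():
            i += 1
        if i >= n_lines or not lines[i].strip().startswith("positions:"):
            raise MsParseError("expected 'positions:' line", i + 1)
        try:
            fractions = [float(p) for p in lines[i].split(":", 1)[1].split()]
        except ValueError:
            raise MsParseError("unparseable position fraction", i + 1) from None
        if len(fractions) != segsites:
            raise MsParseError(
                f"{len(fractions)} positions for segsites {segsites}", i + 1
            )
        positions = np.floor(np.asarray(fractions) * sequence_length).astype(np.int64)
        i += 1
        rows: list[np.ndarray] = []
        while i < n_lines:
            line = lines[i].strip()
            if not line or line == "//":
                break
            if len(line) != segsites:
                raise MsParseError(
                    f"haplotype row length {len(line)} != segsites {segsites}", i + 1
                )
            if set(line) - {"0", "1"}:
                raise MsParseError("haplotype row contains non-{0,1} character", i + 1)
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
            i += 1
        if not rows:
            raise MsParseError("replicate has no haplotype rows", i)
        matrices.append(GenotypeMatrix(np.array(rows, dtype=np.int8), positions))
    return matrices


def write_ms(matrices: Sequence[GenotypeMatrix], sequence_length: float) -> str:
    """Serialize genotype matrices in the ms dialect (inverse of read_ms)."""
    out = ["ms-style output", str(len(matrices))]
    for gm in matrices:
        out.append("")
        out.append("//")
        out.append(f"segsites: {gm.n_sites}")
        if gm.n_sites:
            fracs = " ".join(f"{p / sequence_length:.6f}" for p in gm.positions)
            out.append(f"positions: {fracs}")
            for row in gm.alleles:
                out.append("".join(str(int(x)) for x in row))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# succinct tree-sequence (tskit) import
# ---------------------------------------------------------------------------


def _perturb_time_ties(times: dict[int, float], parent_of: dict[int, int]) -> dict[int, float]:
    """Nudge exact parent/child time ties upward by TIME_TIE_EPSILON.

    Processes nodes in ascending time order, so a chain of ties resolves into
    strictly increasing times.
    """
    adjusted = dict(times)
    children = {}
    for c, p in parent_of.items():
        children.setdefault(p, []).append(c)
    for node in sorted(adjusted, key=lambda i: adjusted[i]):
        for c in children.get(node, ()):
            if adjusted[node] <= adjusted[c]:
                adjusted[node] = adjusted[c] + TIME_TIE_EPSILON
    return adjusted


def record_from_tskit(
    ts,
    provenance: str = "true_simulation",
    label=None,
    max_trees: int | None = None,
    rng: np.random.Generator | None = None,
    downsample_mode: str = "window",
) -> TreeSequenceRecord:
    """Convert a tskit.TreeSequence into a TreeSequenceRecord.

    Per-branch mutation counts are taken from the mutation table (the count
    of mutations whose node is the child of the edge, within each tree's
    interval).  ``max_trees`` optionally applies the downsampling cap at
    construction time so that node objects are only built for surviving
    trees; ``original_num_trees`` always reflects the full sequence.
    """
    import tskit  # local import: core module stays importable without it

    n = ts.num_samples
    sample_ids = list(ts.samples())
    pop_of = {}
    for s in sample_ids:
        p = ts.node(s).population
        pop_of[s] = 0 if p in (-1, tskit.NULL) else int(p)
    total_trees = ts.num_trees

    keep: list[int] | None = None
    if max_trees is not None and total_trees > max_trees:
        if rng is None:
            raise ValueError("max_trees requires a seeded rng")
        if downsample_mode == "window":
            start = int(rng.integers(0, total_trees - max_trees + 1))
            keep = list(range(start, start + max_trees))
        elif downsample_mode == "span_weighted":
            spans = np.array([t.interval.right - t.interval.left for t in ts.trees()])
            probs = spans / spans.sum()
            keep = sorted(rng.choice(total_trees, size=max_trees, replace=True, p=probs))
        else:
            raise ValueError(f"unknown downsample mode {downsample_mode!r}")
        keep_set = set(keep)
    else:
        keep_set = None

    # mutation counts per (tree_index, child_node)
    mut_count: dict[tuple[int, int], int] = {}
    for site in ts.sites():
        pos = site.position
        tree_index = ts.at(pos).index
        for mut in site.mutations:
            key = (tree_index, mut.node)
            mut_count[key] = mut_count.get(key, 0) + 1

    trees: list[MarginalTree] = []
    kept_indices: list[int] = []
    for tree in ts.trees():
        idx = tree.index
        if keep_set is not None and idx not in keep_set:
            continue
        if tree.num_roots != 1:
            raise TreeSequenceError(f"tree {idx} has {tree.num_roots} roots")
        parent_of: dict[int, int] = {}
        times: dict[int, float] = {}
        for u in tree.nodes():
            times[u] = tree.time(u)
            p = tree.parent(u)
            if p != tskit.NULL:
                parent_of[u] = p
            if not tree.is_leaf(u) and tree.num_children(u) != 2:
                raise TreeSequenceError(
                    f"tree {idx}: node {u} has {tree.num_children(u)} children (non-binary)"
                )
        times = _perturb_time_ties(times, parent_of)
        nodes = []
        for u in sorted(times):
            leaf = tree.is_leaf(u)
            nodes.append(
                Node(
                    id=u,
                    time=0.0 if leaf else times[u],
                    is_leaf=leaf,
                    population=pop_of.get(u, UNKNOWN_POPULATION) if leaf else UNKNOWN_POPULATION,
                    mutations_above=mut_count.get((idx, u), 0),
                )
            )
        left, right = tree.interval.left, tree.interval.right
        trees.append(MarginalTree(nodes=nodes, parent_of=parent_of, interval=(left, right)))
        kept_indices.append(idx)

    if keep is not None:
        # duplicates in span-weighted draws: rebuild in draw order
        by_idx = {i: t for i, t in zip(kept_indices, trees)}
        trees = [by_idx[i] for i in keep]
        # surviving intervals no longer tile [0, L); featurization only
        # consumes midpoints and span fractions of the retained trees
        k_pop = max(pop_of.values()) + 1 if pop_of else 1
        return TreeSequenceRecord(
            trees=trees,
            sequence_length=ts.sequence_length,
            n_samples=n,
            k_populations=k_pop,
            provenance=provenance,
            label=label,
            original_num_trees=total_trees,
        )

    k_pop = max(pop_of.values()) + 1 if pop_of else 1
    return TreeSequenceRecord(
        trees=trees,
        sequence_length=ts.sequence_length,
        n_samples=n,
        k_populations=k_pop,
        provenance=provenance,
        label=label,
        original_num_trees=total_trees,
    )


# ---------------------------------------------------------------------------
# text dialect: "left<TAB>right<TAB>newick" per line
# ---------------------------------------------------------------------------


def _parse_newick(newick: str):
    """Minimal Newick parser returning (parent_of, branch_length, leaf_names).

    Node ids are assigned in parse order; only leaf labels are retained.
    Branch lengths are required on every non-root node.
    """
    s = newick.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0
    next_id = [0]
    parent_of: dict[int, int] = {}
    blen: dict[int, float] = {}
    leaf_name: dict[int, str] = {}
    children_count: dict[int, int] = {}

    def new_node() -> int:
        i = next_id[0]
        next_id[0] += 1
        return i

    def parse_clade() -> int:
        nonlocal pos
        node = new_node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                parent_of[child] = node
                children_count[node] = children_count.get(node, 0) + 1
                if pos >= len(s):
                    raise TreeSequenceError("unbalanced parentheses in Newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise TreeSequenceError(f"unexpected character {s[pos]!r} in Newick")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",();":
            pos += 1
        label = s[start:pos]
        if node not in children_count and label:
            leaf_name[node] = label.split(":", 1)[0]
        if ":" in label:
            blen[node] = float(label.split(":", 1)[1])
        elif node not in children_count and not label:
            raise TreeSequenceError("unlabeled leaf in Newick")
        return node

    root = parse_clade()
    if pos != len(s):
        raise TreeSequenceError(f"trailing characters in Newick: {s[pos:]!r}")
    for node in parent_of:
        if node not in blen:
            raise TreeSequenceError("missing branch length in Newick")
    for node, c in children_count.items():
        if c != 2:
            raise TreeSequenceError(f"non-binary Newick node with {c} children")
    return root, parent_of, blen, leaf_name


def _tree_from_newick(
    left: float,
    right: float,
    newick: str,
    leaf_order: list[str] | None,
    population_of_leaf: dict[str, int] | None,
) -> tuple[MarginalTree, list[str]]:
    root, parent_of, blen, leaf_name = _parse_newick(newick)
    children: dict[int, list[int]] = {}
    for c, p in parent_of.items():
        children.setdefault(p, []).append(c)
    # leaf depth -> node times (leaves at 0)
    depth: dict[int, float] = {root: 0.0}
    order = [root]
    while order:
        u = order.pop()
        for c in children.get(u, ()):
            depth[c] = depth[u] + blen[c]
            order.append(c)
    leaves = [u for u in depth if u not in children]
    max_depth = max(depth[u] for u in leaves)
    for u in leaves:
        if abs(depth[u] - max_depth) > 1e-6 * max(1.0, max_depth):
            raise TreeSequenceError("leaves are not contemporaneous (ultrametricity violated)")
    raw_times = {u: max_depth - depth[u] for u in depth}
    for u in leaves:
        raw_times[u] = 0.0
    raw_times = _perturb_time_ties(raw_times, parent_of)

    def name_key(nm: str):
        # numeric labels (the writer uses node ids) sort numerically
        return (0, int(nm)) if nm.isdigit() else (1, nm)

    names = sorted((leaf_name[u] for u in leaves), key=name_key)
    if leaf_order is None:
        leaf_order = names
    name_to_row = {nm: i for i, nm in enumerate(leaf_order)}
    if set(leaf_name.values()) != set(leaf_order):
        raise TreeSequenceError("trees do not share a single leaf set")
    # re-id: leaves get ids 0..n-1 by leaf_order; internals n.. by time
    internals = sorted((u for u in depth if u in children), key=lambda u: raw_times[u])
    new_id = {}
    for u in leaves:
        new_id[u] = name_to_row[leaf_name[u]]
    for j, u in enumerate(internals):
        new_id[u] = len(leaves) + j
    nodes = []
    for u in sorted(depth, key=lambda u: new_id[u]):
        leaf = u in leaves
        pop = 0
        if leaf and population_of_leaf is not None:
            pop = population_of_leaf[leaf_name[u]]
        nodes.append(
            Node(
                id=new_id[u],
                time=raw_times[u],
                is_leaf=leaf,
                population=pop if leaf else UNKNOWN_POPULATION,
                mutations_above=0,
            )
        )
    remapped_parent = {new_id[c]: new_id[p] for c, p in parent_of.items()}
    return MarginalTree(nodes=nodes, parent_of=remapped_parent, interval=(left, right)), leaf_order


def load_tree_sequence(
    path,
    dialect: str = "auto",
    mutation_table=None,
    population_of_leaf: dict[str, int] | None = None,
    k_populations: int | None = None,
) -> TreeSequenceRecord:
    """Load a tree sequence from a .trees (succinct) or text-dialect file.

    Text dialect: one tab-separated line per tree, ``left  right  newick``,
    "#" comments allowed; branch lengths in generations.  ``mutation_table``
    is an optional iterable (or path to a tab-separated file) of
    ``(tree_index, child_id, mutation_count)`` rows.
    """
    path = str(path)
    if dialect == "auto":
        dialect = "tskit" if path.endswith(".trees") else "text"
    if dialect == "tskit":
        import tskit

        return record_from_tskit(tskit.load(path))
    if dialect != "text":
        raise TreeSequenceError(f"unknown dialect {dialect!r}")

    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    trees: list[MarginalTree] = []
    leaf_order: list[str] | None = None
    for ln in lines:
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            parts = ln.split(None, 2)
        if len(parts) != 3:
            raise TreeSequenceError(f"text dialect expects 'left right newick': {ln!r}")
        left, right = float(parts[0]), float(parts[1])
        tree, leaf_order = _tree_from_newick(
            left, right, parts[2], leaf_order, population_of_leaf
        )
        trees.append(tree)
    if not trees:
        raise TreeSequenceError("no trees in file")

    if mutation_table is not None:
        if isinstance(mutation_table, (str, bytes)) or hasattr(mutation_table, "__fspath__"):
            rows = []
            with open(mutation_table, "r", encoding="utf-8") as fh:
                for ln in fh:
                    if not ln.strip() or ln.lstrip().startswith("#"):
                        continue
                    t, c, m = ln.split()
                    rows.append((int(t), int(c), int(m)))
            mutation_table = rows
        for t_idx, child, count in mutation_table:
            tree = trees[t_idx]
            tree.nodes = [
                Node(v.id, v.time, v.is_leaf, v.population, int(count))
                if v.id == child
                else v
                for v in tree.nodes
            ]

    n = trees[0].n_leaves
    if k_populations is None:
        k_populations = (
            max(v.population for t in trees for v in t.nodes if v.is_leaf) + 1
        )
    record = TreeSequenceRecord(
        trees=trees,
        sequence_length=trees[-1].interval[1],
        n_samples=n,
        k_populations=k_populations,
        provenance="inferred",
    )
    problems = validate_record(record)
    if problems:
        raise TreeSequenceError("invalid tree sequence: " + "; ".join(problems[:5]))
    return record


def _canonical_ids(tree: MarginalTree) -> dict[int, int]:
    """The id scheme the text loader assigns: leaves 0..n-1 in sorted-label
    order, internals n.. by ascending time."""
    leaves = sorted((v for v in tree.nodes if v.is_leaf), key=lambda v: v.id)
    internals = sorted((v for v in tree.nodes if not v.is_leaf), key=lambda v: (v.time, v.id))
    out = {v.id: i for i, v in enumerate(leaves)}
    out.update({v.id: len(leaves) + j for j, v in enumerate(internals)})
    return out


def write_text(record: TreeSequenceRecord, path, mutation_table_path=None) -> None:
    """Write the text dialect (inverse of load_tree_sequence's text branch).

    Node ids are remapped to the loader's canonical scheme so the optional
    mutation-count companion table round-trips exactly.
    """

    def newick_of(tree: MarginalTree, canon: dict[int, int]) -> str:
        children = tree.children_of()
        times = {v.id: v.time for v in tree.nodes}

        def render(u: int) -> str:
            if u not in children:
                return f"{canon[u]}"
            a, b = children[u]
            return f"({render(a)}:{times[u] - times[a]:.9f},{render(b)}:{times[u] - times[b]:.9f})"

        return render(tree.root.id) + ";"

    canons = [_canonical_ids(tree) for tree in record.trees]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# left\tright\tnewick (branch lengths in generations)\n")
        for tree, canon in zip(record.trees, canons):
            fh.write(f"{tree.interval[0]:.9f}\t{tree.interval[1]:.9f}\t{newick_of(tree, canon)}\n")
    if mutation_table_path is not None:
        with open(mutation_table_path, "w", encoding="utf-8") as fh:
            fh.write("# tree_index\tchild_id\tmutation_count\n")
            for t, (tree, canon) in enumerate(zip(record.trees, canons)):
                for v in tree.nodes:
                    if v.mutations_above:
                        fh.write(f"{t}\t{canon[v.id]}\t{v.mutations_above}\n")
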