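# Methods

## Data model

A locus is an ordered list of rooted binary marginal trees whose half-open
genomic intervals tile `[0, L)` (0-based bp coordinates).  All leaves sit
at time 0 (present-day sampling; ancient samples are unsupported); internal
node times are coalescence times in generations.  Each non-root node
carries the count of mutations on the branch to its parent.  Exact
parent/child time ties are forbidden because the log-age feature and the
time-ordered node sequence both need strictly increasing internal times;
loaders resolve ties by nudging the later node upward by 1e-6 generations
(processed in ascending time order so chains of ties resolve
monotonically).  Non-binary trees are rejected rather than resolved — the
inference tools this package consumes emit strictly binary trees.

ms-dialect simulator text is parsed with fractional positions mapped to bp
as `floor(p·L)`; collisions are kept as distinct columns (the alignment
path never uses bp positions).  Succinct tree-sequence files are read
through tskit; a plain-text dialect (per line: left, right, Newick in
generations, plus an optional tab-separated mutation-count table keyed by
canonical node ids) covers fixtures and interchange.

## Featurization

Node features: `F = 2 + k + 1` per node — z-scored log age (leaves fixed
at 0 *after* normalization; the normalization pool contains internal nodes
only), z-scored branch mutation count (pooled over all nodes, the root
included with count 0), and the one-hot role block.  The 12-dim tree
summary vector is [TMRCA; mean/median/sd of the n−1 coalescence times;
mean/median/sd/skew/max of the 2n−2 branch lengths; interval midpoint
scaled to (0,1); span fraction; total branch length].  Conventions: sd is
population-normalized (ddof 0), skew is the biased Fisher–Pearson moment
coefficient g1 (0 when the variance vanishes), even-count medians average
the central pair.  The total branch length occupies the 12th slot so that
the 37-dim global vector (mean, sd, median of the tree summaries + the
original tree count) is consistent with the architecture's declared
shapes; it is a natural whole-tree size statistic not already present.
Every normalized channel (including the global vector's tree-count slot)
is z-scored with statistics fitted on the training split only; an sd below
1e-12 is replaced by 1 and recorded, so constant channels map to 0.

Downsampling of sequences longer than the cap (default 128 trees; 64 in
the desk-scale configuration) either keeps a contiguous window with a
uniformly drawn start or, for the sweep task, draws `cap` trees with
replacement with probability proportional to genomic span and restores
original order (duplicates retained).  The pre-downsampling tree count is
preserved for the global vector and for breakpoint accounting (`T − 1`
observable recombination events).  For large simulated datasets the cap is
applied during record construction so that peak memory is one replicate's
tree objects; the record-level downsampling operator has the same
semantics and is what the tests exercise.

## Architecture

Node embedding (`F→26`, an arbitrary but fixed width), skip-concat with
raw features, six graph-attention convolution layers at width `26+F`
(additive skip, LayerNorm over features, ReLU), a second skip-concat
(`26+2F`), a single-layer unidirectional GRU over the node ordering
(leaves in sample order, then internals by time), concat of the 12-dim
tree summary, a second GRU over the padded tree axis with true lengths
masked (hidden states stop updating past each sequence's length, making
outputs provably padding-invariant), concat of the affinely embedded
(37→37) global vector, then two fully connected layers with ReLU and
batch normalization and a linear output head.  Classification outputs are
logits; regression outputs are z-scores of the standardized targets.

Attention follows the "v2" form: scores `aᵀ LeakyReLU(Θ_s x_i + Θ_t x_j)`
(negative slope 0.2, single head), softmax over each node's children plus
its self-loop; the self term of the update uses `Θ_s x_i`, so leaves
(empty neighborhoods) reduce to `Θ_s x_i + bias`.  Conv-layer biases are
enabled.  Cross-entropy is implemented with the conventional negative sign
(a positive quantity to minimize).  Dropout is not used.

Ablation switches: `use_graph_conv` (off: raw node features flow straight
to the per-tree GRU, making the output provably independent of the edge
list), `use_tree_summary`, `use_global_summary`.

Initialization: affine and attention weights uniform fan-in
(U[−1/√fan_in, 1/√fan_in]); recurrent hidden-to-hidden blocks orthogonal;
one global integer seed controls everything.

### Numerical engine

The environment provides no deep-learning framework, so `treegnn.nn`
contains a compact reverse-mode autodiff tape over numpy with fused
single-node implementations of the attention convolution and the GRU
sequence (hand-written backward passes).  Correctness is established two
ways in the test suite: every layer's parameter and input gradients agree
with central finite differences (1e-6 step) and the convolution agrees
with an O(nodes × neighbors) loop evaluation of the update and attention
formulas to 1e-6.  Float32 is used for training, float64 for gradient
checks.  Cyclic garbage collection is suspended inside the training loop
(the tape is acyclic and reference-counted; generational scans of its
thousands of containers would otherwise dominate runtime).  Per-node
scatter/gather reductions go through sparse incidence-matrix products.

## Training and evaluation

Adam (β = 0.9/0.999), batch sizes 16/36/20/30 for
recombination/introgression/sweeps/demography, up to 100 epochs with
early stopping after 10 epochs without strict improvement of the
validation criterion — validation accuracy for classification, negative
validation loss for regression (the natural reading of "validation
performance" for a regression task) — and restoration of the
best-validation weights (including batch-norm running statistics).
Regression targets are log-scaled then z-scored with training-split
statistics; the recombination simulator already emits log r, which is
z-scored linearly.  RMSE and R² are reported on the log scale (the
back-transform through the target sd is exact); classification reports the
row-normalized argmax confusion matrix, trapezoidal ROC AUC, and step-wise
(non-interpolated) average precision for the declared contrasts: sweeps —
"sweep (hard+soft posterior mass) vs. unselected" and "hard vs. soft";
introgression — "introgressed vs. none" and direction.

## Synthetic data

All coalescent simulation uses msprime with the diploid population-size
convention (`E[pairwise coalescence] = 2N` generations); per-replicate
seeds derive from the dataset seed by a fixed multiplicative-hash counter
(always < 2^31), so datasets are reproducible and extensible.

* **Recombination**: N uniform on {1000, 2000, 5000, 10000, 20000, 50000},
  L = 20 kb, μ = 1.5e-8, n = 50 haploids (16 in the desk-scale runs),
  r from an exponential truncated to [1e-8, 1e-6].  The exponential's
  pre-truncation mean is not externally constrained; the default 1e-7 is
  the geometric midpoint of the bounds and is config-exposed.  A
  multiplicative shift option on (mean, upper bound) supports
  misspecification experiments.
* **Demography**: three epochs, N0 ~ U[100, 4e4], T1 ~ U[100, 3500],
  N1 ~ U[100, 5000], T2 = T1 + U[1, 3500], N2 ~ U[100, 2e4], n = 50.
  Locus length (100 kb), μ (1.5e-8) and r (1e-8) are this package's
  defaults, chosen as ordinary genome-scale values and config-exposed.
* **Introgression**: a generic two-population isolation model with a
  single pulse (fraction 0.2) at t ~ U(0.3, 0.5) × split time in one of
  two directions or absent, three balanced classes, 20 + 14 haploids on a
  10 kb locus.  The defaults (sizes 1e5, split 5e5 generations) are a
  generic deep-divergence parameterization, not a fit to any species pair;
  all are config-exposed.
* **Sweeps**: selection simulations require an external simulator and are
  ingested from ms files plus a five-class label manifest (hard,
  hard-linked, soft, soft-linked, neutral).  Labels are validated against
  the central-subwindow rule (selected site within the central 1/11 ⇒
  sweep class, outside ⇒ linked class); span-weighted downsampling is
  auto-selected for this task.

What the generator emulates is the *statistical structure* of the four
benchmark conditions — parameter supports, class balance, true marginal
trees with per-branch mutation counts.  It does not emulate genealogy
inference error (unless the external inference adapter is used),
sequencing error, unphased or missing data; passing tests therefore
demonstrate correct mechanics and desk-scale learnability on clean input,
not field accuracy on inferred trees.

The external genealogy-inference adapter shells out to Relate (supplied
with the *means* of the simulated parameter distributions), logs the
invocation, and converts the output to the succinct format via the tool's
own converter.  When the tool is absent it raises an explicit
"external tool unavailable" error; there is intentionally no silent
fallback to true trees.

## Alignment-CNN comparison path

Genotype matrices (rows = haplotypes, binary ancestral/derived) are
right-padded with zeros to a fixed width, or left-aligned-cropped when
over-wide (the crop side is this package's choice, applied
deterministically).  Rows are ordered by seriation: an approximately
minimal open path under cosine distance, built nearest-neighbor from every
start and refined by 2-opt, with exhaustive search as the solver for ≤ 8
rows.  The contract is "approximately minimal path", not bit-compatibility
with any particular routing solver.  Cosine distance to an all-zero row is
defined as 1.  Two-population inputs seriate the first block and align the
second to it by optimal assignment (Hungarian algorithm via scipy);
unequal blocks assign min(count) rows and append the remainder seriated.
The baseline network itself is accounted for exactly as the standard
ResNet34 shape (3×3 basic blocks [3,4,6,3] at widths [64,128,256,512],
batch norms counting weight+bias, 1×1 projections on width changes); with
one input channel and five outputs the itemized counts sum to 21,280,965
learnable parameters, the figure `scripts/acceptance.py` recomputes.

## Problem sizes and numerical choices

The test suite's end-to-end recovery check uses the reduced recombination
configuration: 16 haploids, 20 kb, 3000 training / 500 validation
sequences, tree cap 64, recurrent hiddens 64, Adam at 1e-3 (a learning
rate matched to the small dataset; the full-scale default of 1e-5 is
config-exposed), batch 32, at most 3 epochs — the ranking of validation
loci by predicted log r is already strong after the first epoch.
Tolerances: conv-oracle agreement 1e-6; padding invariance 1e-5 (float32
evaluation); normalization round-trip mean within 1e-6 and sd within
1e-3; downsampling frequencies within 3 Monte-Carlo standard deviations
at 1e5 draws.

## Known limitations

Single attention head and unidirectional recurrences only; no polytomy
support; no VCF ingestion or unphased data; the sweep-class selection
simulator is out of scope (ingestion only); full-scale training to the
original benchmark accuracies is out of scope for a CPU-only package;
recurrent hidden sizes default to 256 but the published parameter totals
of the architecture this follows cannot be reconciled with that width, so
no parameter-count claim is made for the graph network itself (the count
is still itemized and internally consistent).
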