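# treegnn

Population-genetic inference directly from sequences of marginal
genealogical trees, using a hybrid graph-attention + recurrent neural
network, with an alignment-CNN comparison path.

## The problem

Modern tools (Relate, tsinfer) infer, from a sample of phased genomes, the
*tree sequence* of a locus: the ordered series of rooted binary genealogies
`T_1, ..., T_T` along the chromosome, adjacent trees separated by the
breakpoints of historical recombination events.  These genealogies encode —
with error — the sample's evolutionary history, so quantities of interest
(the per-bp crossover rate `r`, demographic-model parameters, the presence
and direction of introgression, selective sweeps) should be recoverable
from them directly, without going back through the genotype matrix.

`treegnn` implements a supervised-learning pipeline for exactly this:
coalescent simulation of labelled training data (via msprime), conversion
of tree sequences into graph-learning inputs, a graph neural network over
genealogies, training/evaluation for four benchmark tasks, and the genotype
preprocessing (seriation + optimal assignment) used by the alignment-CNN
comparison path.

## The model

Each marginal tree with `n` leaves is a directed graph on `2n−1` nodes with
`2n−2` child→parent edges.  Node features (`F = 2 + k + 1` for `k`
populations) are the z-scored log coalescence time (0 for leaves), the
z-scored count of mutations on the branch to the parent, and a one-hot
role block over {internal, pop_1, ..., pop_k}.  The network applies, per
tree:

* a node embedding (`F → 26`) with a skip concatenation of the raw features,
* six graph-attention convolution layers (additive skips, LayerNorm, ReLU):

  `x'_i = α_ii Θ_s x_i + Σ_{j∈N(i)} α_ij Θ_t x_j`,

  where `N(i)` are the children of node `i` and the attention weights
  `α_ij` are the softmax over `N(i) ∪ {i}` of
  `aᵀ LeakyReLU(Θ_s x_i + Θ_t x_j)`,
* a GRU over the node sequence (leaves in sample order, then internal
  nodes by time), concatenated with a 12-dimensional per-tree summary
  vector (TMRCA; moments of coalescence times and branch lengths; the
  segment's scaled midpoint and span; total branch length),

and per sequence a second GRU over the (padded, length-masked) trees,
concatenated with a 37-dimensional global summary (mean/sd/median of the
tree summaries plus the original tree count), followed by a
fully-connected head emitting logits (classification) or z-scores
(regression).  Training uses Adam with categorical cross-entropy or smooth
L1 loss and early stopping on validation performance.  Sequences longer
than a cap (default 128 trees) are downsampled: a contiguous random window,
or span-weighted sampling with replacement for the sweep task.

A degree-normalized (non-attention) spectral graph convolution
`X' = D̂^{-1/2} Â D̂^{-1/2} X Θ` is included as an independently testable
reference operator.

All learnable layers (attention convolution, GRUs, normalizations, Adam,
backpropagation) are implemented on numpy via a small reverse-mode
autodiff tape in `treegnn.nn`; gradients are verified against central
finite differences and layer outputs against brute-force per-node formula
evaluations in the test suite.

## Worked example

Reduced recombination-rate task: 600 simulated loci (16 haploid genomes,
20 kb, `μ = 1.5e−8`, `N ∈ {1000, ..., 50000}`, `r` from a truncated
exponential on `[1e−8, 1e−6]`), true trees capped at 64 per sequence,
480/120 train/validation split, recurrent hiddens 64:

```python
import numpy as np
from scipy.stats import spearmanr
from treegnn.pipeline import prepare_splits, simulate_task_dataset
from treegnn.simulate import RecombTaskConfig
from treegnn.nn.model import ArchitectureConfig, TreeSequenceNet, LossSpec
from treegnn.train import TrainConfig, train, predict, evaluate

dataset = simulate_task_dataset("recombination", 600, seed=42,
                                sim_config=RecombTaskConfig(n_samples=16), tree_cap=64)
splits = prepare_splits(dataset, n_train=480, n_validation=120)
model = TreeSequenceNet(
    ArchitectureConfig(n_node_features=4, output_size=1,
                       tree_hidden=64, sequence_hidden=64, head_width=64, tree_cap=64),
    np.random.default_rng(0))
history = train(model, splits.train, splits.validation,
                TrainConfig(learning_rate=1e-3, batch_size=32, max_epochs=3,
                            patience=2, seed=0, loss=LossSpec("smooth_l1")))
report = evaluate(model, splits.validation, "recombination",
                  target_stats=splits.target_stats)
pred = predict(model, splits.validation).ravel()
true = np.array([s.label[0] for s in splits.validation])
print(f"RMSE (log r): {report.rmse[0]:.3f}")
print(f"R^2  (log r): {report.r_squared[0]:.3f}")
print(f"Spearman rho: {spearmanr(pred, true).statistic:.3f}")
```

Output from this configuration:

```
RMSE (log r): 0.501
R^2  (log r): 0.732
Spearman rho: 0.900
```

i.e. after three epochs on 480 examples the network already explains ~73%
of the variance in the natural-log crossover rate and ranks validation
loci by rate with Spearman ρ = 0.90.  (Accuracy keeps improving with more
replicates and epochs.)

The same pipeline is scriptable from the shell:

```bash
treegnn run --config my_run.yaml --stage simulate
treegnn run --config my_run.yaml --stage featurize
treegnn run --config my_run.yaml --stage train
treegnn run --config my_run.yaml --stage evaluate
```

Every stage writes a provenance manifest (config hash, seed, library
versions) that chains back to the stage that produced its inputs.

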