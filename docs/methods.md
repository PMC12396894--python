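# Methods

`fcgnn` implements a complete connectome-classification analysis: synthetic
case–control cohorts of functional-connectivity (FC) matrices, per-subject
k-nearest-neighbour brain graphs, three graph-neural-network classifiers
(GCN, GAT, SAGPool), perturbation-based connection-importance ranking, and
large-scale-network attribution with clinical-score correlation. This note
records the models, the assumptions, and the design choices that were
genuinely open.

## Graph representation

A subject's FC matrix holds Fisher-transformed Pearson correlations
(z = arctanh r) between the BOLD time series of `n` cortical regions
(default 100, Schaefer-convention names with 17-network labels aggregating
to eight groups: VN, SM, DAN, VAN, LMB, CN, DMN, TPN). The self-connection
is defined as 0 before any downstream use — the Fisher z of r = 1 is
infinite, and zeroing the diagonal removes the singularity.

The graph G = (V, E, W) has one node per region. Node features are the
*dense* rows of the FC matrix (each node's full nodal-connectivity
profile), while edges come from k-NN sparsification: each node selects its
k most strongly connected neighbours and the directed selections are
symmetrized by union, so every node retains at least its own top-k. Open
choices, surfaced as configuration rather than silently fixed:

* **k is not a principled constant.** Default k = 10 (a standard sparse-
  connectome density at 100 nodes, mean degree between 10 and 20); logged
  prominently by the CLI.
* **"Most strongly connected" is read on the signed Fisher-z scale**
  (hyper- vs hypo-connectivity is a signed contrast); `rank="absolute"`
  ranks by magnitude instead.
* Ties break toward the lower region index, making construction fully
  deterministic.
* Node features keep the dense matrix even though edges are sparse: the
  perturbation analysis scores *all* region pairs regardless of their
  presence among sparse edges, which is only coherent when the dense
  feature matrix is the perturbed object.

## Synthetic cohorts

The generator emulates a matched two-group resting-state study. A target
correlation matrix with block structure (within-network correlation 0.4,
between-network 0.1 — typical resting-state block contrast) is built over
the network assignment of the packaged parcel table; patients' targets are
shifted by the configured planted effects (delta added to the target
correlation of specific region pairs). Each subject's matrix is obtained
by sampling a multivariate-normal time series of length T (default 150
volumes, a common resting-state scan length), computing its Pearson
correlation and Fisher-transforming. Generating time series rather than
sampling correlation matrices directly reproduces the estimation-noise
structure of real FC: the Fisher-z of a sample correlation is
approximately normal with variance 1/(T − 3), so T controls noise realism.

Planted shifts can break positive definiteness; a nearest-PD repair
(eigenvalue clipping at 1e−8, then re-normalization to unit diagonal) is
applied, and generation fails loudly if repair is insufficient. The
analytic `expected_correlation` accounts for the repair, so tests compare
simulation against the post-repair population values.

Demographics are matched pairwise (same sex and site, age within ±2
years). Site effects are *not* simulated by default — matching removes
them by design — but an additive per-site offset is available for
robustness experiments. Clinical scores follow
`score = slope · FC(i, j) + intercept + N(0, sd)` for designated
connections; `coupling_for_target_r` chooses the noise so the population
correlation with the coupled edge hits a requested r, using
sd(FC) ≈ 1/√(T − 3). Scores may be missing per subject (missing-at-random
rate), since clinical scales are typically available only for a subset of
patients.

**Planted-effect topology and the PD constraint.** Where a cohort with
planted discriminative edges is required (tests, acceptance runs), the
default configuration scatters the 10 planted edges over disjoint region
pairs. Scattered shifts of ±0.5 leave the target correlation matrix
positive definite, so the effective group difference equals the nominal
delta exactly. Concentrating the same shifts on a hub region — which
would better mirror how disorder effects present in real connectomes —
makes the target covariance infeasible: the nearest-PD repair shrinks
hub-concentrated deltas of 0.5 to roughly 0.28–0.35. Hub topologies are
therefore available but not the default for calibrated-effect scenarios.

What the generator does **not** emulate: raw fMRI time-series artefacts
(motion, physiological noise), scanner/site covariance structure,
heavy-tailed FC distributions, or heterogeneous effect sizes across
subjects. Passing tests therefore demonstrate correctness of the pipeline
mechanics and statistical calibration under idealized Gaussian FC — not
clinical performance on real cohorts.

## Classifiers

All three architectures map (X, A) — node features (B, N, N) and sparse
weighted adjacency — to two-class probabilities via a graph encoder,
graph-level readout, and softmax head. They are implemented in NumPy on a
small reverse-mode automatic-differentiation engine written for this
package (`fcgnn.autodiff`); gradients are verified against central finite
differences (tolerance 1e−4 in the acceptance contract, ~1e−8 observed).

* **GCN** — two convolutions (128, 64 filters) using symmetric
  normalization D^{−1/2}(A + I)D^{−1/2} with unit self-loops and weighted
  degrees, ReLU, dropout 0.3 between hidden layers, mean readout, linear
  softmax head. Negative Fisher-z edge weights pass through unmodified;
  degrees are floored at 1e−6 before the inverse square root so rare
  negative-degree nodes do not produce NaNs.
* **GAT** — three attention layers (64 units × 16 heads, 64 × 16, 64 × 1)
  with ELU. Per-edge coefficients come from LeakyReLU (slope 0.2) scoring
  with per-node softmax over neighbours plus self-loop; heads concatenate
  in layers 1–2 (the single-head final layer makes concat-vs-average
  moot). Dropout 0.5 on attention weights and 0.6 on node features
  (training only). GAT learns its own coefficients and ignores the input
  edge weights — its mechanism replaces W.
* **SAGPool** — three conv/pool blocks of width 64 (the hierarchical
  variant's usual depth; configurable). Each block convolves (as GCN),
  scores nodes with an auxiliary one-channel graph convolution, keeps the
  top ⌈0.8·N⌉ nodes (ties to the lower index), gates surviving features
  by tanh of their scores, and induces the subgraph on survivors
  (re-normalizing the adjacency per block). Per-block readout is
  concatenated mean and max; a jumping-knowledge **sum** (optionally
  concat) aggregates the blocks before a fully connected head with
  dropout 0.2.

Parameters use seeded Glorot-uniform initialization (explicit and logged,
so every run is bit-reproducible). Checkpoints are a key→array `.npz`
container with a YAML config sidecar.

## Training protocol

Adam on cross-entropy; learning rate 5e−5, batch size 32, 500 epochs,
stratified 8:2 train/validation split, 10 runs with per-run seed
`base_seed + run_index`; no early stopping or schedule. Stratification is
used because the matched case–control design implies balanced evaluation.
Validation accuracy, sensitivity and specificity (patients positive) are
reported per run at the final epoch; the checkpoint with the highest
validation accuracy during training (ties to the later epoch) is retained
and is the model used for explanation. Both final-epoch and best-epoch
accuracies appear in the results manifest.

**Desk-scale budgets.** The full protocol (500 epochs, 10 runs) is a
long-running configuration. Tests and the acceptance script use scaled
runs — tens of epochs, 3 seeds, cohorts of 20–80 subjects per group, and
20–100 regions — chosen so each scenario still exercises the full
pipeline. At such budgets the paper-scale learning rate of 5e−5 moves the
parameters by only ~1e−2 in 200 Adam steps and the model stays at chance;
short-budget runs therefore use a learning rate of 3e−3, set once as the
desk-scale training rate (at which a 50-epoch SAGPool run on an 80+80
planted cohort reaches validation accuracies around 0.75–0.81). All rates
are plain configuration (`TrainConfig.lr`).

## Perturbation-based explanation

For each of the n(n−1)/2 unordered region pairs, entries (i, j) and
(j, i) of every subject's dense feature matrix are replaced by a single
global substitution value — three times the highest connection strength
observed across all subjects (signed maximum; a magnitude-based variant
and a per-connection variant exist behind flags) — the model is
re-evaluated, and the influence is RMSE between original and perturbed
probability outputs over all subjects and both classes. The k-NN
adjacency is held fixed (an optional rebuild mode re-sparsifies after
perturbation for sensitivity analysis). Influence maps from multiple
trained models are averaged unweighted; the ranking is descending with
lexicographic tie-breaks, and the top-20 slice feeds attribution.

The production sweep runs through a fused evaluation kernel that exploits
the fact that a single-connection perturbation changes the first block's
pre-activations by a rank-2 update: the first convolution is computed
once per sweep, pairs are processed in fused batches, and the symmetric
normalization is folded into the convolution operands. The kernel is
tested for exact agreement with the straightforward per-pair forward
pass. Sweeps may run in float32 (roughly halving memory traffic);
float32/float64 RMSE values agree to single precision, far below ranking
resolution.

**What the perturbation can and cannot localize.** Because the
classifiers are permutation-equivariant, they recognise discriminative
structure through feature *coordinates* (which regions' connectivity
values carry group signal), not through node identities. The RMSE of pair
(i, j) therefore decomposes approximately into a sum of two separable
terms — node-i sensitivity times coordinate-j weight plus the converse —
so any pairing of two implicated regions scores comparably to a truly
altered pair. Empirically, on cohorts with effects planted on disjoint
region pairs, the top of the ranking names the planted *regions* reliably
but pairs them near-arbitrarily (typical pair-level recovery 1–2 of 10 in
the top-20, against ~0.04 expected under random ranking), and rankings
show the characteristic "family" pattern — many top connections sharing
one region — also visible in published top-connection lists from this
family of methods. Edge-level conclusions from the ranking should
therefore be read as statements about the incident regions; resolving
*which* pairs among the implicated regions differ is beyond the
statistic's resolution at these training budgets.

## Attribution and clinical statistics

The top-k connections contribute 2k region endpoints, counted **with
multiplicity** (a region in several connections counts each time); the
tally by network group and its percentages (count/2k × 100) form the
attribution report. Clinical correlation tests each (connection, score)
pair across subjects with a non-missing score (pairwise deletion, per-test
n reported): Pearson by default, Spearman when *either* variable fails a
Shapiro–Wilk normality test at α = 0.05 (the gate is applied per variable
and the chosen method recorded per test, since which variable triggered
the switch is otherwise ambiguous). Bonferroni correction uses the family
size m = (number of scores) × (number of connections), recomputed from the
actual report contents. Reports are rendered as schema-validated JSON plus
TSV/text, with no timestamps so identical inputs give byte-identical
output.

## Numerical choices

* Fisher transform rejects |r| ≥ 1; sampled correlations are clipped at
  1 − 1e−12 before arctanh (an event of measure zero in practice).
* Matrices are symmetrized (z + zᵀ)/2 after transformation to remove
  floating-point asymmetry.
* Eigenvalue clipping floor for PD repair: 1e−8; weighted-degree floor in
  normalization: 1e−6.
* All tie-breaks (k-NN neighbours, pooling survivors, ranking) resolve
  toward the lower index, so every stage is deterministic given seeds.
* Cross-entropy uses the log-sum-exp form; the softmax backward uses the
  Jacobian-vector product directly.

## Known limitations

* The NumPy engine is single-threaded and dense; it is sized for
  ~100-node graphs and desk-scale cohorts, not for thousands of subjects
  or voxel-level graphs.
* GAT at the full 16-head width is memory-heavy in training; the test
  suite exercises contracts at reduced widths (the contracts are
  size-independent).
* Edge-level explanation inherits the coordinate-resolution limit
  described above; node-level or gradient-based attribution is out of
  scope.
* The packaged 100-region parcel table is a synthetic stand-in following
  the Schaefer 17-network naming convention (all regions named in the
  packaged top-20 lists are present with correct labels; the remainder
  are convention-consistent fillers). Analyses of real data should load
  the official parcel table for their atlas via `ParcelTable.from_tsv`.
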