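# Methods

## Model

A bipartite graph G(V, P, E) with |V| = M row nodes and |P| = N column
nodes is modelled as a random dot product graph: each node carries a
latent position (x_i or y_j in R^d) and edges are independent Bernoulli
draws with Pr(A_ij = 1) = x_i · y_j. This requires every pairwise dot
product to lie in [0, 1] — a geometric constraint on the latent space —
and identifies positions only up to a common orthogonal transformation
of both sides (any rotation/reflection applied jointly leaves all
probabilities unchanged). Consequently the package never interprets
absolute coordinates; coordinate-level diagnostics go through an
orthogonal Procrustes alignment, and all probability-level quantities
are rotation-invariant by construction.

## Spectral embedding

Positions are estimated by adjacency spectral embedding: with the SVD
A = LΣRᵀ, the rank-d truncation gives V̂ = L̂ Σ̂^(1/2), P̂ = R̂ Σ̂^(1/2),
so V̂P̂ᵀ is the Frobenius-optimal rank-d approximation of A
(Eckart–Young). Implementation notes:

- Dense LAPACK SVD below 500 nodes on the larger side; the iterative
  sparse solver (`scipy.sparse.linalg.svds`, tolerance 1e-10) above.
  One extra singular value is computed to warn when the truncation
  boundary falls inside a tied pair (the retained subspace is then not
  unique).
- Sign canonicalisation: for each singular-vector pair, the
  largest-magnitude entry of the left vector is made positive. Any fixed
  convention is valid under the orthogonal non-identifiability; this one
  makes outputs deterministic across runs and backends.
- Estimated dot products can leave [0, 1]; they are clipped there when
  interpreted as probabilities. Latent coordinates themselves are never
  clipped — only probabilities.
- "Variability explained" in scree summaries is cumulative squared
  singular values over total squared (Frobenius energy); an unsquared
  variant is available via `scree(..., squared=False)`.

The retained dimension can be chosen by the Zhu–Ghodsi
profile-likelihood elbow: for each split point q, the ordered singular
values are modelled as two Gaussian groups with separate means and a
pooled variance (denominator p − 2, floored at 1e-12·max σ² and at
float-tiny so degenerate inputs stay defined), and the q maximising the
log-likelihood is returned, smallest q winning ties — a constant scree
therefore yields 1.

*Limitation.* The elbow criterion presumes a scree with separated
signal values. On Bernoulli-sampled RDPG graphs of a few hundred nodes
with weak secondary dimensions, the trailing latent singular values sit
at or below the Marchenko–Pastur noise bulk, the scree decays smoothly,
and the criterion's output is essentially arbitrary (it may return 1 or
a mid-bulk rank). The automatic selection is therefore trusted only
where an elbow is visible; the synthetic studies fix d at the known
generative dimension.

## Metadata encoding

Categorical variables expand to full one-hot blocks (no reference class
dropped); continuous variables are centred and scaled by constants
computed on the model-training nodes only and reused verbatim for
model-test, validation and new nodes (no leakage). The full one-hot
design is rank-deficient with an intercept; the linear family handles
this with the minimum-norm least-squares solution, so a single encoder
serves all three model families. An encoder spec is frozen at fit time;
re-applying it is bit-reproducible, and an unseen categorical class is a
hard error naming the variable and class rather than a silent zero.

## Metadata → latent regression

Three families map the encoded metadata to the d latent coordinates:

- `linear` — exact minimum-norm least squares of Z ≈ [1, X]·B.
- `mlp1` — one dense hidden layer of 200 ReLU units, linear output.
- `nn2` — two dense hidden layers of 250 ReLU units, linear output.

Networks are trained with mini-batch Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8) on mean-absolute-error cost, 30 epochs, batch size 20, and
either a constant learning rate of 0.01 or a time-based decay where the
rate during epoch t (0-based) is exactly 0.01 − 0.0001·t. Weights are
initialised uniform on ±1/√fan_in from the config seed, and the batch
order is reshuffled each epoch from the same seed stream, so a fixed
seed reproduces the training history bit-for-bit. There is no early
stopping: the per-epoch loss on the model-test nodes is recorded so
overfitting is visible in the history rather than silently corrected.
MAE is the training cost; evaluation reports both MAE and MSE (per-cell
means over nodes × coordinates).

The trainer is a self-contained numpy implementation; at these layer
widths and sample sizes a framework would add nothing but weight.

## Splitting protocol

`SplitSpec` holds the study design: a fraction of nodes per side
(default 0.15 each) is held out *entirely* — every incident edge goes to
validation, so these "new" nodes are genuinely cold-start, visible only
through metadata. Edges among the remaining observed nodes are split
Bernoulli(0.70) into the training graph vs the observed×observed
validation set; held-out edges appear as zeros in the training
adjacency (the standard link-prediction convention — it biases training
density downward by the held-out fraction, uniformly, which rescales
the embedding but cancels in rank-based evaluation). Observed nodes are
then partitioned 50/50 per side into model-training and model-test
lists for the regression stage. Node counts round down; remainders stay
observed. The dimension d, when selected automatically, is chosen on
the training adjacency only.

Four validation blocks result, named by (row, column) node kinds:
`obs_obs` (out-of-sample pairs of observed nodes, scored with SVD
positions on both sides), `new_obs` and `obs_new` (metadata-predicted ×
SVD), and `new_new` (metadata-predicted on both sides — the full
cold-start case). Every pair in a block is scored — positives are the
held-out links, negatives the non-links among the same node sets; no
negative sampling is applied before the evaluation-stage subsample. The
headline "pooled validation" evaluation pools the three blocks that
involve metadata-predicted positions; the `obs_obs` reconstruction
block is reported per block, since it measures embedding quality rather
than the metadata pathway.

## Evaluation

AUC-ROC is computed in rank (Mann–Whitney) form, ties counting one
half. Sensitivity (tp/(tp+fn)) and accuracy use a hard threshold,
default 0.5 and overridable; zero denominators yield NaN markers. Under
sparse graphs most predicted probabilities fall below 0.5, so
sensitivity at the default threshold is near zero — the threshold is a
reporting convention, not a tuned operating point. Uncertainty follows
a subsample-then-bootstrap protocol: one subsample of 1000 pairs drawn
without replacement (the whole set if smaller), then 2000 stratified
bootstrap replicates — positives and negatives resampled separately
with replacement, preserving class counts — summarised by a percentile
interval at the 95% level. The interval construction (percentile, not
BCa) is recorded in the report.

## Synthetic benchmarks

The generator draws latent coordinates i.i.d. uniform on [0, d^(−1/2)],
which guarantees valid probabilities with nonnegative inner products; an
optional density target rescales both sides by a common factor (error
if the rescale would push any entry of B past 1 — with this law the
attainable mean caps near mean/max ≈ 0.26, the natural density being
0.25). Metadata are W·g(x) + b + Gaussian noise with g the identity
(linear scenario) or the elementwise square (quadratic scenario) and W
a seeded full-rank matrix; categorical columns arise by equal-frequency
quantile binning of a designated continuous column. The quadratic
scenario deliberately omits an identity block: the coordinates are
nonnegative and short-ranged, so alongside an identity block they would
remain linearly recoverable and the scenario would not actually be
nonlinear. With squares only, inverting the metadata map requires a
square root — curved enough that the misspecified linear baseline
plateaus (test MAE ≈ 0.035 at 300 training nodes) while both networks
pass below it (≈ 0.011–0.025).

What the generator does *not* emulate: degree heterogeneity beyond what
the latent law induces, block/community structure, temporal dynamics,
missing metadata, and survey-style measurement artefacts. Passing tests
therefore demonstrate the correctness of the machinery and its
statistical behaviour under the RDPG's own assumptions — not
performance on any particular empirical network.

A consequence of the bounded-uniform latent law worth stating plainly:
the true probabilities are only mildly heterogeneous, so even the
Bayes-optimal scorer — the true matrix B evaluated against its own
Bernoulli sample — reaches AUC ≈ 0.69 at d = 3 (≈ 0.82 at d = 1, lower
as d grows). Absolute AUCs on these benchmarks must be read against
that ceiling; the meaningful quantity is the gap to the oracle
(typically ≤ 0.02 for the metadata-predicted blocks at 300 nodes per
side) and the collapse to ≈ 0.5 when metadata are decoupled by
permutation.

## Problem sizes and numerical choices

The shipped studies use graphs of 100–600 nodes per side: large enough
that spectral concentration and the training protocol behave as in the
asymptotic regime they are designed for, small enough to run in seconds
as part of a routine test cycle. Key tolerances: rank-truncation error
vs the dense-SVD oracle at 1e-8; linear fits vs the pseudoinverse
oracle at 1e-8; rotation invariance of predictions at 1e-10; unclipped
dot products exact to 1e-12. Degenerate inputs are defined rather than
rejected wherever a sensible value exists: all-zero adjacency embeds to
zero positions, a constant scree selects d = 1, an all-zero
configuration Procrustes-aligns with the identity.

## Known limitations

- Clipping to [0, 1] discards the ordering among pairs whose raw dot
  products are negative, creating ties at score 0 that cost a little
  AUC on sparse graphs; no alternative projection is attempted.
- The bootstrap CI covers sampling noise of the evaluation pairs, not
  the variability of the split, the embedding, or network training.
- Automatic dimension selection is unreliable on weakly-spiked screes
  (see above).
- The linear baseline's minimum-norm solution is one of infinitely many
  least-squares solutions on collinear one-hot designs; predictions are
  unique, coefficients are not individually interpretable.
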