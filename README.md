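# rdpglink

Link prediction in bipartite networks from node metadata, using random
dot product graph (RDPG) embeddings.

Bipartite networks — visitors × places, plants × pollinators, hosts ×
parasites — are almost always incompletely observed, and the hardest
prediction problem they pose is the *cold start*: estimating the
interaction probabilities of a node that does not appear in the observed
network at all, only in a metadata table. `rdpglink` implements a
three-step procedure for exactly this setting:

1. **Embed.** Under the bipartite RDPG model, the probability that row
   node *i* links to column node *j* is the dot product of latent
   positions, Pr(A<sub>ij</sub> = 1) = x<sub>i</sub>·y<sub>j</sub>, with
   links as independent Bernoulli draws. The truncated SVD of the
   adjacency matrix, A ≈ L̂Σ̂R̂ᵀ, yields position estimates by splitting
   the square roots of the top *d* singular values between the sides:
   V̂ = L̂Σ̂^½ and P̂ = R̂Σ̂^½ (adjacency spectral embedding). The rank *d*
   can be chosen automatically with the Zhu–Ghodsi profile-likelihood
   elbow on the scree of singular values.
2. **Regress.** A mapping from encoded node metadata (full one-hot
   categoricals + standardised continuous variables) to the latent
   positions is fitted on a model-training split of nodes and monitored
   on a model-test split. Three families are provided: a minimum-norm
   linear baseline (cold-start formula x*<sub>n+1</sub> = β₀ +
   m<sub>n+1</sub>·β), a one-hidden-layer perceptron (200 ReLU units)
   and a two-hidden-layer network (250 + 250 ReLU units), trained by
   mini-batch Adam on mean-absolute-error cost for 30 epochs with batch
   size 20, under a constant (0.01) or time-decayed (−0.0001/epoch)
   learning rate.
3. **Predict.** Any pair's interaction probability is the clipped dot
   product clip₀¹(x·y); a brand-new node is first projected into the
   latent space through the fitted mapping. Predictions are scored with
   rank-based AUC-ROC, sensitivity and accuracy, with percentile
   confidence intervals from a class-stratified bootstrap (1000-pair
   subsample, 2000 replicates by default).

A synthetic-data module generates fully reproducible RDPG benchmarks —
latent positions whose dot products are valid probabilities by
construction, Bernoulli-sampled graphs, and metadata tables that are
noisy linear or quadratic transforms of the latent coordinates,
optionally quantile-binned into categorical variables — so the whole
procedure is testable without any external dataset.

## Worked example

```python
import rdpglink as rl

scenario = rl.SyntheticScenario(M=300, N=300, d_true=3, noise_sd=0.1, seed=1)
truth = rl.make_benchmark(scenario)
model = rl.RdpgLinkPredictor.from_benchmark(truth, d=3,
                                            split_spec=rl.SplitSpec(seed=1))
results = model.fit()
print(results.summary())
```

```
RDPG link prediction results
================================================================
graph: 300 x 300 nodes, 24210 links
training graph: 255 x 255 nodes, 12084 links
new nodes held out: 45 rows, 45 cols
latent dimension d = 3 (fixed)
top singular values: 52.565, 12.557, 12.256
mapping family: row=linear, col=linear
----------------------------------------------------------------
mapping MAE (model-train / model-test):
  row: 0.1285 / 0.1472
  col: 0.1353 / 0.1397
----------------------------------------------------------------
validation blocks (pairs scored / links held out / AUC):
  obs_obs :   52941 /   5265 / 0.6236
  new_obs :   11475 /   3247 / 0.6363
  obs_new :   11475 /   3077 / 0.6484
  new_new :    2025 /    537 / 0.5921
```

15% of the nodes on each side (45 of 300) were removed from the network
entirely; the `new_*` rows show that their links are recovered well
above chance from metadata alone — e.g. AUC 0.64 for new visitors
against observed places, and 0.59 for pairs where *both* nodes are new.
Under this generator the Bayes-optimal scorer (the true probability
matrix itself) reaches about 0.69, so these are close to the attainable
ceiling, which is set by how heterogeneous the true probabilities are,
not by the method. The bootstrap evaluation adds uncertainty:

```python
report = results.evaluate(blocks=("new_obs", "obs_new", "new_new"), seed=1)
print(report.to_json())
# "auc": 0.6358...,  "auc_ci": [0.5994..., 0.6724...],  "n_sampled": 1000, ...
```

The same run is available from the shell:

```sh
rdpglink run --config config.yaml --seed 1 --out-dir out/
```

with subcommands `simulate`, `split`, `embed`, `select-dim`, `fit-map`,
`predict` and `evaluate` exposing the individual stages.

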