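# nbsbm — network-based sparse Bayesian machine

`nbsbm` predicts whether a cancer cell line (or patient sample) is
**sensitive** or **resistant** to a drug from its gene-expression profile,
and — just as importantly — reports *which connected sub-networks of genes*
drive the prediction.  It is aimed at the common situation in pharmacogenomics
where the feature dimension (thousands of genes) dwarfs the sample count
(tens of cell lines), but a disease-specific signaling network is available
as prior knowledge.

## The model

For samples `x_i ∈ R^{d+1}` (expression plus a leading bias 1) and labels
`y_i ∈ {−1, +1}` (+1 = sensitive), the classifier is linear, `y = sign(βᵀx)`,
with three Bayesian ingredients:

1. **Label-noise-robust likelihood.**  Observed labels are flipped with
   probability ε, giving per-sample likelihood

   ```
   p(y_i | β, ε, x_i) = ε (1 − H(y_i βᵀx_i)) + (1 − ε) H(y_i βᵀx_i),
   ```

   with `H` the Heaviside step.  The likelihood depends only on which side
   of the hyperplane a sample falls — it counts errors, it does not weigh
   them — so single outliers cannot dominate the fit.  ε gets a Beta(a₀, b₀)
   prior (defaults a₀ = 1, b₀ = 8, prior mean 1/9) truncated to [0, ½].

2. **Spike-and-slab sparsity.**  Each weight carries a binary inclusion
   indicator `z_j`: `β_j = 0` exactly when `z_j = 0`, and `β_j ~ N(0, σ_j²)`
   (the slab) when `z_j = 1`.

3. **Markov-random-field network prior.**  The indicators are coupled
   through the gene network `G` via

   ```
   p(z | G, λ, γ) ∝ exp( λ Σ_j z_j − γ zᵀ L z ),
   ```

   where `L` is the degree-normalized graph Laplacian.  λ controls overall
   sparsity; γ ≥ 0 rewards configurations in which network neighbours are
   included or excluded together, encoding the assumption that connected
   genes are jointly relevant or jointly irrelevant.

Posterior inference is by **expectation propagation** (EP): a full-covariance
Gaussian over β, Bernoullis over z, and a Beta factor over ε, refined by
damped cavity/moment-matching updates (one site per observation, per gene and
per network edge).  Two brute-force reference posteriors — exhaustive
enumeration over z with Monte-Carlo/quadrature integration, and a blocked
Gibbs sampler — live in `nbsbm.oracle` and anchor the EP implementation in
the test suite.  Genes ranked by posterior inclusion probability
`P(z_j = 1 | data)` and thresholded into connected components yield the
predictive sub-network biomarkers.

## Worked example

```python
import nbsbm as nb
from sklearn.metrics import roc_auc_score

# a modular gene network and expression data with one predictive module,
# planted weights of +-1, and 10% of the labels flipped
net = nb.generate_network(n_modules=6, module_size=10, p_intra=0.3, p_inter=0.02, seed=7)
ds, truth = nb.generate_dataset(net, n_samples=120, n_active_modules=1,
                                effect_size=1.0, flip_rate=0.1, seed=7)

cfg = nb.ModelConfig(grids=nb.GridSpec(n_lambda=5, n_gamma=5), ep=nb.EPControls(seed=7))
model = nb.fit(ds, net, cfg)                       # standardize + grid search + EP
print(model.chosen_lambda, model.chosen_gamma)     # 0.2231 0.6065
print(model.training_error)                        # 0.083
print(nb.noise_estimate(model.posterior))          # 0.098   (true flip rate 0.1)
print(roc_auc_score(truth.true_support,
                    model.posterior.incl_prob))    # 0.878   (support recovery)

nb.rank_features(model.posterior).head(3)
#     gene  incl_prob  beta_mean
# m05_g059   0.998443   2.015137
# m05_g057   0.998281   1.938155
# m05_g054   0.997569  -2.031619
```

The hyperparameters are chosen by the lowest training error rate on log-even
grids (λ over [e⁻⁵, e²], γ over [e⁻⁵, e¹]); the flip-rate estimate lands on
the true 10% contamination; and the top-ranked genes all come from the
planted module `m05` — the "network as a biomarker" readout.  Module
extraction at the default threshold 0.5 returns that module as one connected
component (23 genes, mean inclusion 0.68 in this run).

The same pipeline is scriptable from a shell:

```bash
nbsbm simulate --modules 6 --module-size 10 --n 120 --active 1 \
      --effect 1.0 --flip 0.1 --seed 7 --out data/
nbsbm cv  --expr data/expression.tsv --labels data/labels.tsv \
      --network data/network.tsv --folds 5 --repeats 5 --seed 17 --out report/
nbsbm fit --expr data/expression.tsv --labels data/labels.tsv \
      --network data/network.tsv --out model/
```

`cv` runs the evaluation protocol (stratified 5-fold × 5-repeat
cross-validation with per-fold standardization and model selection, vertical
ROC averaging, paired Wilcoxon comparisons); `fit` writes the posterior,
a ranked gene table, GMT gene sets and a GraphML predictive subgraph.

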