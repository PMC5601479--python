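# deepcox

Deep Cox proportional-hazards networks for right-censored survival data:
feed-forward networks trained by backpropagating the Cox partial log
likelihood, with Bayesian hyperparameter optimization, Harrell's c-index
evaluation, gradient-based model interpretation ("risk backpropagation"),
multi-cohort merging for transfer learning, and a proportional-hazards
simulator so everything is testable end to end without external data.

It is aimed at biostatisticians and computational biologists who want to
model patient survival from moderate-to-high-dimensional feature tables
(clinical variables, expression, copy number, mutations) without
hand-selecting features, and who need the resulting nonlinear model to
remain interpretable.

## The model

Each patient i has a feature vector, an observed time Y_i (event or
follow-up) and an event indicator c_i (1 = event observed, 0 =
right-censored; U denotes the uncensored set).  A network maps features
through H hidden layers (ReLU or tanh, optional dropout) into a linear Cox
output layer; the predicted **risk** is the linear score X_i β of the final
activations (no exponential).  Training minimizes the negative log partial
likelihood

    l(β, X) = − Σ_{i∈U} ( X_i β − log Σ_{j∈R_i} e^{X_j β} ),

where R_i = { j : Y_j ≥ Y_i } is the risk set (Breslow handling of ties).
Its gradient with respect to the per-patient scores,

    ∂l/∂X_i = c_i β − Σ_{j∈U, i∈R_j} β e^{X_i β} / Σ_{k∈R_j} e^{X_k β},

is backpropagated through the hidden layers; optimization is full-batch
gradient descent with a backtracking (Armijo) line search, one update per
epoch, because the partial likelihood couples patients through the risk
sets.

Because training a single network is expensive, the design —
layers 1–5, width 10–1000, dropout fraction 0–0.9, ReLU vs tanh — is chosen
by Bayesian optimization: a Gaussian-process surrogate of validation
c-index with expected-improvement acquisition, on a 60/20/20
train/validation/test randomization.  Accuracy is reported as Harrell's
c-index (1 = perfect concordance, 0.5 = chance), repeated over randomized
splits.

Trained models are interpreted by **risk backpropagation**: the per-patient
feature risk score is the gradient of predicted risk with respect to each
input, ∂R/∂f = β × Π_h J_h with J_h the hidden-layer Jacobians.  For a
linear model this is β for every patient; for a deep model the scores vary
across patients, tracing the nonlinear risk surface.  Cohort-level feature
rankings use the median score per feature; a ranked list can be exported in
the two-column preranked format consumed by gene-set enrichment tools.

## Worked example

```python
import numpy as np
from deepcox import (SimulationSpec, simulate_survival, split_train_val_test,
                     NetworkConfig, train, predict_risk, concordance_index,
                     feature_risk_scores, rank_features)

spec = SimulationSpec(n=600, p=8, censoring_target=0.6, seed=7)
ds, true_risk = simulate_survival(spec)
print(f"censored fraction: {1 - ds.events.mean():.2f}")

sp = split_train_val_test(ds, seed=0)
fit = ds.subset(np.concatenate([sp.train_idx, sp.val_idx]))
test = ds.subset(sp.test_idx)

model = train(fit, NetworkConfig(n_hidden_layers=1, layer_width=16,
                                 activation="tanh", dropout_frac=0.1,
                                 max_epochs=200, init_seed=0))
res = concordance_index(predict_risk(model, test), test.times, test.events)
print(f"test c-index: {res.c_index:.3f} over {res.n_permissible_pairs} pairs")

ranked = rank_features(feature_risk_scores(model, ds))
print(ranked.head(3).to_string(index=False))
```

prints

```
censored fraction: 0.61
test c-index: 0.880 over 3729 pairs
feature  median_score  rank
     f4     -0.931492     1
     f5      0.894710     2
     f7      0.741212     3
```

The simulated cohort is 61% right-censored with a sign-alternating
linear log-hazard (coefficients ±0.7).  A one-hidden-layer tanh network
reaches c-index 0.88 on the held-out 20% — close to the true-risk optimum
for this design — and risk backpropagation recovers the generating signal:
f4 (true coefficient −0.7) is ranked protective, f5 (+0.7) risk-increasing.

The same workflow is available from the shell:

```bash
deepcox simulate --n 600 --p 8 --censoring 0.6 --seed 7 --out sim/
deepcox evaluate --input sim/data.tsv --n-repeats 20 --budget 15 --out eval/
deepcox train    --input sim/data.tsv --out model.json
deepcox interpret --model model.json --input sim/data.tsv --out interp/
```

`evaluate` writes a tidy per-repeat results table plus the best design;
`interpret` writes the per-patient risk-score matrix, the ranked feature
table, and a `.rnk` preranked list.

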