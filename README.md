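# micox

Outcome-guided mutual-information gene networks and network-regularized
Cox survival regression, with the full survival-prediction evaluation
protocol (time-dependent AUC, risk-group log-rank testing, cross-validated
hyperparameter selection) and a synthetic-cohort generator for testing.

## Who this is for

Researchers building survival models from high-dimensional genomic
profiles (expression, copy number, methylation) who want the gene network
behind a network-regularized Cox model to be *informed by the clinical
outcome* rather than by co-expression or a static interaction database.

## The method

**Network construction.** The clinical outcome is binarized into
short-term (≤ 36 months) and long-term (> 36 months) survival; patients
censored before the threshold are dropped, since their long-term status is
unknown. Every unordered gene pair is scored by the mutual information

&nbsp;&nbsp;&nbsp;&nbsp;I(X₁, X₂; Y) = H(X₁, X₂) + H(Y) − H(X₁, X₂, Y)

between the pair, treated as one composite discrete variable (equal-width
histogram discretization), and the binary outcome Y. This joint statistic
detects interaction effects — gene pairs that predict outcome together
while each member alone is uninformative — that no marginal or
gene–gene-only measure can see. A permutation threshold θ (outcome labels
permuted, pair scores averaged per pair, maximum taken over pairs) gives a
base cutoff, amplified by a significance factor: the network G_σ keeps
edges with I ≥ θ(1 + σ).

**Regression.** Coefficients β of the Cox proportional-hazards model
h(t|X) = h₀(t)·exp(X′β) are estimated by maximizing the penalized partial
log-likelihood

&nbsp;&nbsp;&nbsp;&nbsp;pl(β) − (λ/2)·β′Γβ,&nbsp;&nbsp; Γ = (1 − α)(I − S) + αI,

where S = R^(−1/2) G_σ C^(−1/2) is the degree-normalized adjacency of the
network. The quadratic form shrinks the *differences* between coefficients
of connected genes (a normalized-Laplacian smoothness penalty,
½ΣS_ij(β_i − β_j)² plus ridge); at α = 1 it reduces to plain L2 (ridge)
Cox. The baseline hazard is recovered with the Breslow estimator, and
patients are ranked by the prognostic index PI = X′β̂.

**Evaluation.** Time-dependent AUC with cumulative cases / dynamic
controls, a 40%/40% high/low-risk split by PI with the two-group log-rank
test, Kaplan–Meier curves, and an 80/20 holdout protocol with 5-fold CV
over the (σ, λ, α) grid — networks and thresholds are re-estimated inside
each training fold, so no information leaks from held-out samples.

## Worked example

```python
import numpy as np
from micox import (SimulationSpec, simulate, OutcomeGuidedMINetwork,
                   NetCoxSurvival, td_auc, split_risk_groups, logrank_test)

spec = SimulationSpec(n_samples=300, n_genes=22, n_modules=2, module_size=4,
                      n_interaction_pairs=1, seed=11)
ds = simulate(spec)
train, test = np.arange(200), np.arange(200, 300)
surv_train, surv_test = ds.survival.subset(train), ds.survival.subset(test)

builder = OutcomeGuidedMINetwork(n_bins=3, n_perm=100, sigma=0.0, random_state=11)
builder.fit(ds.expression.iloc[train], surv_train)
print(f"theta = {builder.theta_:.4f}; edges kept at sigma=0: "
      f"{builder.network_.n_edges} of {builder.complete_network_.n_edges}")

model = NetCoxSurvival(lam=0.01, alpha=0.5, network=builder.network_)
model.fit(ds.expression.iloc[train], surv_train)
pi = model.predict(ds.expression.iloc[test])
auc = td_auc(pi, surv_test)
groups = split_risk_groups(pi, ids=surv_test.sample_ids, fraction=0.40)
stat, p = logrank_test(groups, surv_test)
print(f"holdout mean time-dependent AUC = {auc.mean_auc:.3f}")
print(f"log-rank chi2 = {stat:.1f}, p = {p:.2e}")
```

Output:

```
theta = 0.0405; edges kept at sigma=0: 153 of 231
holdout mean time-dependent AUC = 0.897
log-rank chi2 = 71.5, p = 2.80e-17
```

The permutation cutoff θ ≈ 0.04 bits removes about a third of the 231
candidate edges; the network-penalized model ranks held-out patients with
a mean time-dependent AUC of 0.90, and the top-40%/bottom-40% risk groups
separate decisively (log-rank p ≈ 3·10⁻¹⁷) — as expected on a cohort
simulated with genuine planted signal.

## Command line

```
micox simulate      --n-samples 300 --n-genes 40 --seed 0 --out-dir data/
micox build-network --expression data/expression.tsv --clinical data/clinical.tsv \
                    --sigma 0.1 --out net.tsv
micox fit           --expression data/expression.tsv --clinical data/clinical.tsv \
                    --network net.tsv --lam 0.01 --alpha 0.5 --out model.tsv
micox evaluate      --expression data/expression.tsv --clinical data/clinical.tsv \
                    --model model.tsv --out report.json
micox cv            --expression data/expression.tsv --clinical data/clinical.tsv \
                    --seed 0 --out-dir cv/
```

All formats are tab-separated text; see `micox.io` docstrings for the
exact schemas.

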