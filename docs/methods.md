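# Methods

## Model and estimation

The hazard of patient i with gene profile X_i is h(t | X_i) =
h₀(t)·exp(X_i′β). Coefficients are estimated by Newton–Raphson on the
penalized partial log-likelihood pl(β) − (λ/2)β′Γβ, with the baseline
hazard profiled out (the standard Cox route) and recovered afterwards by
the Breslow estimator h₀(t) = d(t) / Σ_{j∈R(t)} exp(X_j′β̂). Ties are
handled Breslow-style everywhere — all events at one time share a risk
set — for consistency with the Breslow baseline. The solver starts at
β = 0, uses step-halving so the objective never decreases across
accepted iterations, solves Newton systems with a symmetric positive
solve (1e−10 ridge jitter on factorization failure), and stops when the
gradient max-norm or the relative objective change falls below 1e−8
(max 100 iterations; a non-converged fit is returned with
`converged_ = False` and a warning). The log-sum-exp terms are shifted
by max(Xβ) for stability. The solver is deterministic; no seed is
involved.

The penalty matrix is Γ = (1 − α)(I − S) + αI with
S = R^(−1/2) A C^(−1/2), where A is the adjacency of the gene network,
R and C its row/column sums. A is binary by default — the filtered
network is a *set* of significant pairs, and an edge either survived
filtering or it did not — with an option to carry MI weights instead.
Isolated genes get zero rows/columns in S, so their penalty degenerates
to plain ridge; this keeps Γ positive definite (all eigenvalues ≥ α)
for any graph. The ½ in (λ/2)β′Γβ matches the ridge-Cox convention used
by scikit-survival and glmnet; it only rescales the λ grid.

## Information statistics

All entropies are empirical plug-in estimates in bits. Continuous gene
values are discretized into equal-width histogram bins spanning
[min, max] (default B = 3 bins; the maximum value is assigned to the top
bin; constant genes collapse to a single bin with zero entropy rather
than erroring, since flat features occur in real profiles). The pair
statistic I(X₁, X₂; Y) treats (X₁, X₂) as one composite variable with up
to B² states. Bin counts are sorted before the entropy sum so the
floating-point result is exactly invariant to cell relabeling, which
makes the statistic exactly symmetric under swapping the pair members.

The outcome is binarized at 36 months (3 years, configurable): label 1
if survival exceeds the threshold, 0 otherwise. Patients censored before
the threshold carry no usable label and are excluded — from network
construction always, and from the Cox fit by default
(`CVConfig.filter_for_cox`, which can be turned off to retain them for
regression only; whether such patients should inform the regression at
all is genuinely ambiguous, and the flag records the choice).

## Permutation threshold θ and the σ filter

For each of n_perm (default 100) uniformly random permutations of the
outcome labels, all pair scores are recomputed; each pair's scores are
averaged over permutations, and θ is the maximum of these per-pair
means. Edges with I ≥ θ(1 + σ) survive; σ ≥ 0 tightens the cutoff and
ties at the cutoff are kept (≥). The complete MI matrix and θ are
computed once per dataset or fold and re-thresholded across the σ grid,
so the σ sweep repeats none of the O(p²·n) work. The all-pairs
computation itself runs in per-gene blocks of bincount scatters,
O(p²·n) plus O(p²·B²) table work; the package targets desk-scale
problems (p up to a few hundred).

θ is deliberately a *base* cutoff, not a strict significance bound:
averaging over permutations drives each per-pair mean toward the null
expectation of the MI estimate, and because that null is right-skewed a
sizeable minority of truly null pairs still exceeds the maximum of the
means at small p. This is intrinsic to the definition — and is exactly
the role of the σ amplification, which exists to tighten the filter
beyond θ. The tests therefore assert the provable property (strictly
sub-half null exceedance, monotone tightening in σ) rather than a fixed
small false-edge rate.

An alternative reading of the threshold — average over pairs within a
permutation, then maximum over permutations — is not implemented; the
per-pair-mean reading is the one this package commits to.

## Evaluation

Time-dependent AUC uses cumulative cases ({i : t_i ≤ t, δ_i = 1}) and
dynamic controls ({i : t_i > t}); patients censored by t are excluded at
that t. AUC(t) is the Mann–Whitney concordance of case scores over
control scores with ties counted ½ (equivalent to the trapezoidal area
under the empirical ROC built from the strict f(X) > c convention).
Evaluation times default to the distinct observed event times; times
where either set is empty are skipped, and the summary is the unweighted
mean over the remaining times. Inverse-probability-of-censoring
weighting is deliberately not applied; the plain empirical estimator is
the documented choice.

Risk groups take the top and bottom floor(0.4·n) patients by prognostic
index (ties broken by stable input order); the two groups are compared
with the standard two-group log-rank test ((O₁−E₁)²/V against χ²₁) and
Kaplan–Meier product-limit curves.

## Cross-validation protocol

20% of samples are held out (seeded simple random split; a stratified
option exists, off by default). On the remaining 80%, 5-fold CV scores
every (σ, λ, α) combination; default grids are λ ∈ {10⁻⁴, 10⁻³, 10⁻²,
10⁻¹}, α ∈ {0.1, 0.3, 0.5, 0.7, 0.9, 1} and σ ∈ {0, 0.05, …, 0.3} plus
the complete network (σ is selected jointly with λ and α in one grid).
Within each fold the discretization, MI matrix, θ, network, penalty and
coefficients are all built from the four training folds only. The
configuration with the best fold-averaged mean time-dependent AUC wins;
exact ties resolve toward larger α, then larger λ (stronger
regularization). The winner is refit on the full training set and scored
once on the holdout.

## Synthetic cohorts

The generator emulates the data structure the method assumes, scaled to
desk size (defaults: 300 patients × 40 genes, against the
10⁴-gene/340-patient scale of real multi-profile cohorts):

* **Correlated modules.** Genes in a module load on a shared latent
  factor (within-module correlation ρ = 0.5) and share one coefficient
  value drawn with sd 0.5 — a coefficient vector that is smooth over the
  module graph, the structure the Laplacian penalty rewards. Genes
  outside modules have β = 0.
* **XOR interaction pairs.** Each interaction gene carries a latent
  state z ∈ {−1, +1}; its observed value is 1.5·z plus unit Gaussian
  noise (bimodal, like an alteration present/absent state), and the pair
  contributes 0.8·z₁·z₂ to the log hazard. The product is independent of
  each member, so the pair is jointly informative about the binarized
  outcome while each gene is marginally silent — the sharpest test of
  the pair statistic. The bimodal construction matters: equal-width bins
  cannot resolve a median split of a unimodal Gaussian, so a dichotomy
  planted only in the signs would be invisible to the discretization.
* **Survival.** Event times come from exponential or Weibull baselines
  by inverse-transform sampling of S(t|x) = exp(−H₀(t)eᵑ); censoring
  times are exponential with the rate solved (Brent) so the expected
  censored fraction matches the target (default 0.3); times are scaled
  to a months-like range.

All randomness flows from the single spec seed. What the generator does
*not* emulate: realistic marginal distributions of copy-number or
methylation values, batch effects, missingness, or dependent censoring —
so passing tests demonstrate correctness of the machinery and behavior
under the assumed model, not performance on real cohorts.

## Study conditions used in the heavier checks

The network-benefit comparison fits the true module network (α = 0.1,
following the observation that outcome-guided networks prefer small α)
against ridge (α = 1) at matched λ = 20 on 120 training / 120 test
samples with p = 60. λ = 20 ≈ 0.17·n puts the fit in the
regularization-active regime where a prior can matter — with the λ
values appropriate for 10⁴ genes applied to a 60-gene problem the
penalty is inert and the two models coincide. The same reasoning sets
the λ used when checking that CV prefers α < 1 on network-smooth data.
Planted-pair recovery uses 22-gene, 400-patient cohorts with one XOR
pair and no modules (231 candidate pairs, top-1% = top 2).

## Known limitations

* Dense p × p penalty algebra and all-pairs MI limit the package to a
  few hundred genes; the real-data scale of the method needs sparse
  matrices and a chunked MI engine.
* The plug-in MI estimator is biased upward at small n; the permutation
  threshold compensates only on average.
* L1/elastic-net penalties, time-varying covariates, stratified Cox and
  competing risks are out of scope.
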