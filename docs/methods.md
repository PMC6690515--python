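# Methods

## Generating model

The synthetic-data module emulates a 3-arm dietary study in growing mice
with body weight (grams) at weeks 1, 7, 14, 21, 28. The compiled parameter
table (`rmcov/data/table1.csv`) carries, per treatment × time cell, a null
mean (shared across arms: 160, 480, 630, 724, 800 g), an alternative mean
(arm-specific trajectories), an SEM, and an SD. The SDs are the SEMs scaled
by √12, the donor study's group size; this conversion n is fixed at 12 even
when the simulated group size is 3 or 6, because the SDs describe the
population the parameters were extracted from, not the simulated design.
Two quirks of the compiled table are kept verbatim rather than recomputed:
the week-28 null mean is 800 although the three alternative means average
796.7, and the printed SDs differ from SEM·√12 by up to ~0.2% (rounding in
the source extraction). They are the declared generating parameters.

Each replicate draws, per arm, `n_per_group` independent T-vectors from a
multivariate normal. The covariance is built from **that arm's** SD column
with the scenario's structure (heterogeneous CS or heterogeneous AR(1)) and
a shared ρ, so under the null the arms share means but not covariance scale.
The AR(1) lag is the *index* difference of time points, not the week
difference — correlation between weeks 1 and 7 equals that between weeks 21
and 28. Draws use an explicit Cholesky factor of the covariance for
platform-stable streams. There is no missingness, dropout, or truncation;
negative weights are theoretically possible at week 1 (a ~1e-8 tail) and
kept as-is.

What the generator does **not** emulate about real data: non-normal errors,
unbalanced or missing designs, serial measurement error, or covariance
structure outside the CS/AR families. Passing tests therefore demonstrate
properties of the analysis methods under exactly these normal, balanced,
structured conditions — not robustness beyond them.

### Randomness

Counter-mode seeding: every replicate's seed derives from
`SeedSequence(base_seed, spawn_key=(structure, hypothesis, n, round(rho*1e6),
rep_index))`, so any replicate is reproducible in isolation and in any
order. The 48-scenario grid assigns each scenario its own derived base seed.
A frozen test vector in the suite pins the derivation against accidental
change.

## Fitting

The fixed-effect model is the saturated cell-means parameterization (15
parameters), which avoids reference-level ambiguity and makes the GLS
estimates equal the per-cell sample means exactly in balanced data,
regardless of the working covariance. Fitted covariance structures are
pooled across arms (a single σ set), so the "correct" model is correct in
*form* while the generator is arm-specific in scale; this mirrors standard
practice, where a single residual structure is specified for all subjects.

With S the pooled within-group cross-product matrix, N subjects and G arms,
the restricted log-likelihood is

    l_R(Sigma) = -1/2 [ (N−G) log|Sigma| + tr(Sigma⁻¹ S)
                        + Σ_g T log n_g + (N−G) T log 2π ],

maximized by L-BFGS-B over an unconstrained reparameterization: log σ per
time (heterogeneous) or one log σ (homogeneous), and a scaled logit mapping
ρ onto its positive-definite range — (−1/(T−1), 1) for CS, (−1, 1) for
AR(1). Estimated ρ may therefore be slightly negative on null data even
though the *generator* only uses ρ ∈ [0, 1). Starting values are the
per-time pooled SDs and the mean lag-1 within-subject correlation;
convergence requires the optimizer's own success plus a gradient bound
scaled by the criterion magnitude (finite-difference gradients inherit the
criterion's scale, so an absolute bound would misflag converged fits). Up
to 3 jittered restarts are attempted; non-converged replicates are excluded
from rejection-rate denominators, and a warning fires if exclusions exceed
1% in any scenario (in practice, at n = 12 none occur). The unstructured
fit uses its closed form S/(N−G); profile ML is available behind
`method="ml"`.

## Inference

Treatment, time, interaction and per-time-point tests are Wald F statistics
`(Lβ̂)'(L V̂ L')⁻¹(Lβ̂)/rank(L)` on the cell means, with
`V̂ = blockdiag(Σ̂/n_g)`. The per-time-point "treatment effect" is the
joint 2-df equality contrast of the three arm means at that time (a single
p-value per time point); pairwise single-df tests are additionally exposed.
The pairwise SEM at time t is `sqrt(Σ̂_tt (1/n_a + 1/n_b))` — ρ-free,
because arms are disjoint subject sets. Under a homogeneous structure it is
constant across time points; under a heterogeneous one it tracks σ̂_t.

Denominator df default to the Satterthwaite approximation: the asymptotic
covariance of the covariance parameters comes from the numeric Hessian of
the REML criterion, and multi-df contrasts are handled by eigendecomposing
`L V̂ L'` and combining per-component dfs (the standard eigenvector-
component construction). `ddf="residual"` (NT − GT) and
`ddf="between-within"` (N−G for between-subject contrasts, (N−G)(T−1) for
within) are available for sensitivity; at n = 12 all three give denominator
df ≥ 30 and near-identical rejection rates. The separate per-time ANOVA is
the classical one-way F on (G−1, G(n−1)) df with `SEM = sqrt(2·MSE/n)`; no
multiplicity correction is applied across time points, since the quantity
of interest is the raw per-time rejection rate.

## Evaluation conventions

Rejection uses strict `p < α` with α = 0.05. P-value histograms use 20
right-open bins of width 0.05 (last bin closed), normalized by converged
replicate count, so the first bin equals the rejection rate. All three
analysis methods see the identical replicate datasets (common random
numbers), which sharpens method contrasts without biasing any individual
rate. Uniformity of null p-values is checked with a one-sample
Kolmogorov–Smirnov test against Uniform(0, 1).

## Problem sizes

Scenario evaluation at the headline conditions (n = 12, 1000 replicates,
two REML fits plus five ANOVAs per replicate) takes ~15 s per scenario on
one CPU. The test suite exercises the two representative scenarios at 1000
replicates, a scaled-down 200-replicate re-run, Monte-Carlo moment checks
at 2000 simulated replicates, and parameter recovery over 1000 fits; the
acceptance script runs the two representative scenarios at the full 1000
replicates.

## Design choices where the design was open

- **Estimator shape.** The fit is exposed as a sklearn-style estimator
  (`RepeatedMeasuresGLS`) with `fit`/fitted attributes; the module-level
  functions are thin wrappers.
- **Joint vs pairwise per-time contrast.** The per-time treatment effect is
  reported as the joint 2-df test (one p-value per time point); pairwise
  results are exposed but not used in the headline summaries.
- **Convergence bookkeeping.** Exclusion of non-converged fits from
  denominators (with manifest counts) rather than imputation or failure.
- **`build_covariance` ρ domain.** The public builder enforces the
  simulation range ρ ∈ [0, 1); the fitter opts into the wider
  positive-definite range via `rho_range="pd"`.
- **KS result type.** `uniformity_check` returns the package's F-test
  result container with df fields set to (1, sample size) as placeholders,
  keeping one result type across tests.

## Known limitations

- Satterthwaite df rely on numeric differentiation; in tiny samples (n = 3)
  with 6 covariance parameters the approximation—and REML itself—is rough,
  and small-sample rejection rates for the *overall* tests can drift above
  nominal. The calibration claims in the test suite are made at n = 12.
- Kenward–Roger df, unbalanced/missing-data likelihoods, random-effects
  (G-side) formulations, and arm-stratified fitted covariances are out of
  scope.
- The unstructured fit reports conventional residual df (its parameters are
  not scalar-parameterized for the Satterthwaite machinery).
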