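# Methods

This note documents the statistical machinery in `ps5med`: the model, the
three pipeline steps, the tunable parameters and their defaults, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Model and causal estimands

The observed data are N i.i.d. samples of (X, M, Y, C): a scalar exposure
(continuous or 0/1), p mediators, a continuous outcome, and l ≥ 0
covariates. The structural model is linear-Gaussian:

    Y = C'β_C + X β_X + M'β_M + ε_Y,    ε_Y ~ N(0, σ²)
    M = α_C C + X α_X + ε_M,            ε_M ~ N_p(0, Σ_M),  ε_Y ⫫ ε_M

with no exposure–mediator interaction. Under the standard sequential
ignorability assumptions (no unmeasured exposure–outcome,
mediator–outcome, exposure–mediator confounding, plus the cross-world
assumption), the natural direct effect is β_X, the natural indirect
effect is NIE = Σ_j α_Xj β_Mj, and TE = NDE + NIE. Derived summaries:

- **GM%** = NIE / TE — the mediated share of the total effect. TE is
  estimated once from the full data by regressing Y on [1, C, X]; it
  involves no selection, so splitting it would only discard efficiency.
  When |TE| < 1e-10 the ratio is reported as NaN with a warning.
- **NR** = 1 − IE / (|IE⁺| + |IE⁻|) — the fraction of absolute mediation
  mass canceled between positive and negative per-mediator contributions
  α_Xj β_Mj. The formula presumes IE ≥ 0; for a dominant negative IE we
  apply it to the sign-flipped contributions, which keeps NR in [0, 1]
  and makes it invariant to an overall sign change. An all-zero vector
  yields NR = 0 by convention.

Per-mediator products α_Xj β_Mj are reported as *mediation
contributions* — the active mediation level of a mediator, not an
individually identified causal effect.

All regressions include an intercept, and residual (co)variances use
unbiased denominators (n − #parameters); the distinction from the MLE
denominators is immaterial for the plug-in Monte-Carlo p-values.

## Step 1: splitting, residualization, MCP selection

The sample is split uniformly at random into halves D1/D2 (odd N puts the
extra row in D2, the inference half). Marginal exposure effects are
removed from Y and from each mediator by simple regressions on [1, X]
over **all** N rows — these regressions involve no selection, so using
the full sample costs nothing, and covariates deliberately stay out of
them (they enter the penalized criterion directly). Residualization
stabilizes selection when strong exposure effects on many mediators
induce collinearity.

Selection minimizes on D1

    Σ_i (μ_Yi − C_i'β_C − μ_Mi'β_M)² + Σ_j P(β_Mj; λ, a)

with the minimax concave penalty P(t; λ, a) = λ|t| − t²/(2a) for
|t| ≤ aλ, constant beyond. Covariates are unpenalized (handled exactly by
projection, per Frisch–Waugh); mediators are standardized to unit
variance within the fitting rows and coefficients returned on the
original scale. The coordinate-descent solver (numba-compiled, with
active-set sweeps and warm starts along a descending log-spaced ladder of
100 penalty values from λ_max down to 0.01·λ_max) uses the
firm-thresholding update exact for standardized columns; convergence is
declared when the largest coefficient change in a sweep falls below
1e-7 · max(1, ‖β‖∞), capped at 10 000 sweeps. The concavity parameter
defaults to a = 3.

**Penalty-level rule.** The default selects λ by minimizing the extended
BIC (EBIC, γ = 1) along the full-D1 path, restricted to supports that
keep at least three observations per fitted parameter. Two facts drive
this choice, both visible in the simulation regimes this package targets
(50 moderate outcome signals spread over p ≫ n candidates):

1. The non-convex path exhibits a *phase transition*: once warm starts
   accumulate enough true mediators, the solution snaps to the oracle
   support, and the in-sample fit improves abruptly. K-fold CV on
   penalized fits misses this because each fold's path (smaller n)
   transitions at a fold-specific λ, so the pooled CV curve favors
   under-selection — which inflates σ̂² on D2 through omitted signal,
   biases the IE estimate downward, and makes the null draws
   over-dispersed (conservative p-values).
2. At very small λ the path behaves like greedy best-subset search and
   nearly interpolates the response with ~n/2 adaptively chosen columns,
   which defeats any purely likelihood-based criterion; the
   ≥3-observations-per-parameter restriction keeps that regime out of
   consideration.

Plain k-fold CV on the penalized fits remains available
(`selection_criterion="cv"`, 10 folds by default) for dense,
well-separated problems.

Guard rails: the selected size is additionally capped at
⌊|D2|/2⌋ − l − 2 so the D2 outcome regression stays well-posed (if the
criterion's choice exceeds the cap, λ moves up the ladder to the smallest
feasible value); an empty selection is recorded as "no mediators
selected" and contributes p_global = 1 and IE = 0 to aggregation — an
empty model is evidence of no mediation on that split, and discarding it
would bias the aggregate.

## Step 2: partial-sum inference

On D2 restricted to the selected set M′ (size q), the outcome regression
yields β̂_M with covariance σ̂²·(Gram⁻¹)_MM. The mediator regressions —
which involve no selection — are fitted on the full sample, giving α̂_X
with covariance g_xx·Σ̂_M′ (g_xx the exposure entry of the shared design's
inverse Gram). The contribution statistics T_j = |α̂_Xj β̂_Mj| are sorted
descending (ties broken by original column order) and accumulated into
partial sums PS_k = Σ_{j≤k} T_(j)^γ, k = 1..q. Small k targets sparse
signals, large k dense ones; the family is tested jointly, so the unknown
sparsity need not be guessed. Note the test targets Σ|α_j β_j|^γ rather
than the signed sum: exactly canceling contributions (+c, −c) are
detected, and the NR statistic quantifies such cancelation separately.

The null distribution is approximated by the plug-in normal
(α̂, β̂) ~ N_2q(point estimates, blockdiag(Cov α̂, Cov β̂)) — block
diagonal because ε_Y ⫫ ε_M. From B draws, centered statistics
T_j^(b)(0) = |α_j^(b) β_j^(b) − mean_b(α_j^(b) β_j^(b))| are formed, the
null partial sums computed exactly as the observed ones, and

    p_k = (1 + #{b : PS_k^(b) ≥ PS_k}) / (B + 1),

the add-one rule guaranteeing p_k ∈ [1/(B+1), 1] and validity. The same
centered draws give per-mediator marginal p-values
p_Mj = (1 + #{b : T_j^(b)(0) ≥ T_j}) / (B + 1). (Centered draws are used
for the marginals; the uncentered alternative would center every null at
its own observed value and destroy discrimination.)

The q dependent p-values are combined by the Cauchy combination
T_PS = (1/q) Σ_k tan((0.5 − p_k)π), standard Cauchy under the null even
under dependence; p_global is its upper-tail probability. Inputs are
clipped to [1e-15, 1 − 1e-15] before the tangent transform; for q = 1 the
combination is the identity.

Defaults: γ = 2 (γ ≥ 2 emphasizes strong sparse signals; the package's
own power checks confirm γ = 3 ≥ γ = 1 in a 1-active-of-50 regime),
B = 10 000 for data analysis, B = 1000 in replicated simulations.

## Step 3: multiple splitting and aggregation

R independent splits (default 50; the packaged experiments use R between
8 and 50 depending on the check) are
run with counter-based child seeds derived from the master seed, so
results are bit-identical for any worker count. Aggregation:

- IE, NDE, NR: medians over splits (the paper-level quantity is the
  median-aggregated IE; NR's aggregation is this package's choice).
- Global p-value: the empirical median (type-1, left-continuous order
  statistic: the ⌈0.5R⌉-th smallest), capped at 1. No (1 − log δ)⁻¹
  inflation factor is applied.
- Per-mediator p-values: δ-quantile with δ = 0.5h/R for a mediator
  selected in h of R splits, splits that did not select it counting as
  p = 1. This penalizes rarely selected mediators exactly in proportion
  to their selection frequency.
- Multiplicity: BY (FDR) and Bonferroni (FWER) over the universe m of
  mediators selected at least once — the only ones with a defined
  aggregated p-value. Default reporting threshold q < 0.01.

The type-1 quantile convention is fixed for bit-reproducibility;
Meinshausen-style aggregation is insensitive to it at these R.

Prioritization ranks mediators by aggregated p-value; ties (e.g. several
mediators at the Monte-Carlo floor) break by selection frequency, then by
absolute median contribution.

## Synthetic data

The generator reproduces the simulation design the method was validated
on: X ~ N(0,1) (or Bernoulli(0.5)), ε_Y ~ N(0,1), ε_M ~ MVN(0, Σ_M) with
Σ_M either AR1 (ρ ∈ {0, 0.5}) or identity-with-correlated-pairs
(disjoint consecutive pairs at ρ = 0.9 within the leading 50 columns, so
correlated mediators share a mediation direction). Coefficient regimes:
four composite nulls (complete; dense α ~ U(1,3) / β = 0; sparse α = 0 /
β_{1..50} ~ U(1,3); disjunctive α and β nonzero on disjoint index sets)
— all with Σ α_j β_j = 0 exactly — and the alternative
(β_{1..50} = 1, α_{1..s} = alpha_strength on a grid up to 0.2). U(1,3)
draws are redrawn per replicate, the stricter test of calibration. The
direct effect defaults to β_X = 0.5 (not specified by the design; chosen
so TE ≠ NIE and GM% is non-trivial — type-I error is insensitive to it,
power curves mildly so). Replicate streams use per-index seeds, so
concatenating partial streams reproduces the full stream.

What the generator does **not** emulate: covariates in the simulation
regimes (the pipeline supports them; the study conditions have none),
unmeasured confounding, non-Gaussian noise, nonlinear or interaction
effects, and the spatial structure of imaging mediators. Passing tests on
these data therefore certify the statistical machinery under the model's
own assumptions, not robustness to their violation.

## Operating characteristics and problem sizes

The `evaluate` module reruns the pipeline over replicate streams and
reports: type I error (rejection rate at α = 0.05 and the p-value sample
for Q–Q inspection), power, relative bias of the median-IE estimator
(|mean over replicates of ÎE − IE| / IE — the bias of the estimator, not
the per-replicate absolute error, which at these settings is dominated by
the sampling noise of ~45 α-null selected contributions), top-k
prioritization sensitivity, and the false positive rate among mediators
declared at the BY threshold.

Packaged scales (the package's own desk-scale choices; every experiment
is a pure function of its config and seeds):

- Acceptance script: block-correlation alternative, 20 replicates,
  R = 50, B = 1000 — ~7 min on one CPU.
- Test suite: null calibration at n = 300, p = 300 with 150 replicates
  (sparse) / 50 (dense, disjunctive) at R = 10, B = 500; bias at
  N = 500, p = 1000 with 25 replicates per correlation at R = 8;
  sensitivity at 4 replicates, R = 50.

The solver stops descending the penalty ladder once the support exceeds
the EBIC dof guard — those deeper path points can never be selected, and
they are where the non-convex coordinate descent spends most of its time.

Two empirical notes. First, the aggregated global p-value is conservative
under composite nulls at small per-split sample sizes: with a D1 of 150
rows only part of the 50-signal outcome model is recoverable, omitted
signal inflates σ̂² on D2 and with it the null draws, and some splits
select nothing (contributing p = 1). At the design's native scale
(N = 500, p = 1000) the same pipeline is calibrated under the sparse null
(KS vs uniform 0.096, KS-test p = 0.61, 60 replicates). Second,
under the dense null the selected set is typically empty, so the p-value
distribution has an atom near 1: rejection rates are controlled but the
p-values are not uniform — the cost of the q = 0 fallback, accepted by
design.

## Numerical choices and degenerate inputs

- Rank-deficient designs raise an error naming the offending columns
  (QR pivot check at tolerance n·eps·max diag R).
- Covariance matrices for the null draws are symmetrized and their
  eigenvalues clipped at zero; a matrix negative beyond −1e-8 relative is
  an error.
- Zero-variance mediator columns are excluded from penalization and can
  never be selected; a zero-variance exposure is rejected at load time.
- Monte-Carlo p-values never serialize as 0 (the add-one floor); output
  floats use 17 significant digits for round-trip safety.
- Derived seeds are masked below 2³¹.

## Limitations

- The composite-null conservativeness at the complete null (both α and β
  zero) is intrinsic to the plug-in product-normal approach; an adaptive
  bootstrap would address it at substantial computational cost and is
  deliberately out of scope.
- Selection consistency — and hence the IE estimate's bias — degrades
  when the per-split sample cannot support the true outcome model
  (roughly n/2 ≲ 3·#signals); the EBIC rule then under-selects and the
  IE estimate loses the contributions of unselected actives.
- Mediation contributions of correlated mediators "borrow" signal from
  unselected partners (a selected member of a ρ = 0.9 pair absorbs its
  partner's outcome coefficient), which is what makes the method's
  prioritization robust to collinearity but also means a contribution is
  not an isolated per-mediator causal effect.
- Only continuous outcomes, linear models without exposure–mediator
  interaction, and a single exposure per fit are supported.
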