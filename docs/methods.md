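# Methods

## Model

`phenolta` fits a latent transition model (a hidden Markov model with a
small number of states and categorical emissions) to panels of binary
indicators. For subject *i* with responses *Y_{ijt}* (item *j* = 1…J, wave
*t* = 1…T) and latent class sequence *(S₁,…,S_T)*:

- *S₁* ~ Categorical(δ), δ ∈ Δ^{K−1};
- *S_t | S_{t−1}* ~ row *S_{t−1}* of the transition matrix τ (one τ shared
  across transitions when T > 2);
- *Y_{ijt} | S_t = k* ~ Bernoulli(ρ_{kjt}), independent across items given
  the class (local independence).

ρ is wave-specific by default because measurement of the asthma items is
not assumed invariant over time; a constrained mode (ρ equal across waves)
is available and saves K·J·(T−1) parameters. Missing cells are marginalised
by dropping their Bernoulli factor, which is valid under missingness at
random; a subject with every cell missing contributes log 1 = 0 and
triggers a warning.

### Estimation

EM with an exact E-step via scaled forward–backward recursions. The panel
is first collapsed to its unique response patterns with multiplicities, so
an iteration costs O(#patterns · K²) regardless of n. M-step updates are
the standard weighted-posterior means; δ, τ rows and ρ are clipped to
[10⁻⁶, 1 − 10⁻⁶] and renormalised, so degenerate estimates never produce
infinite logs. Convergence: relative log-likelihood change < 10⁻⁸ or 1000
iterations (the fit is returned with `converged=False` in the latter
case, after a final evaluation so the stored log-likelihood matches the
returned parameters). Initialisation: δ and τ rows from flat Dirichlet
draws, ρ ~ Uniform(0.2, 0.8); 20 restarts by default, all drawn from one
seeded generator, best final log-likelihood wins. The observed-data
log-likelihood is non-decreasing across iterations (EM ascent); the trace
of the winning restart is stored on the fit for verification.

### Label switching

Mixture class labels are arbitrary, so fitted classes are reported in a
canonical order: descending endorsement (ρ binarised at 0.5) of current
diagnosis, then previous diagnosis, then wheeze, at the wave in question,
with the continuous ρ values as tie-breakers. Binarising first makes the
order robust to sampling noise in near-zero probabilities. On study-like
fits this orders the phenotypes as (diagnosis with symptoms, previous
diagnosis, symptoms only).

One subtlety matters for T = 2 with wave-specific ρ: permuting the
follow-up class labels — τ's columns together with wave-2 ρ — leaves the
likelihood unchanged, so the two waves' labels are identified only up to
independent permutations. Canonical ordering therefore orders each wave
independently in that case; with T > 2 (shared τ) or constrained ρ a
single permutation is applied. Without the per-wave ordering, transition
tables can silently cross-label the waves.

### Model selection

BIC = −2 log L + p log n with p = (K−1) + K(K−1) + K·J·T (ρ unconstrained).
The subject count n enters the penalty (not the number of cells). The
lowest BIC wins; exact ties go to the smaller K (parsimony). A failed fit
at one K is recorded in the selection table and skipped.

## Modal assignment and patterns

Per-wave posteriors P(S_t = k | Y) come from the same forward–backward
pass; each subject is assigned the modal class per wave, ties toward the
lowest canonical index. The per-wave marginal is the default because the
assignment is defined per time point; jointly-most-probable sequence
decoding (Viterbi) is available as `method="sequence_modal"` and agrees
with the marginal assignment on well-separated fits.

The (baseline, follow-up) modal pair maps to a longitudinal pattern via a
configurable table rather than code, because the grouping of rare
off-diagonal transitions is a reporting decision, not a modelling fact.
The default table sends every transition *into* the diagnosis+symptoms
class to "persistent diagnosis with persistent/incident symptoms", the
improvement route (diagnosis+symptoms → previous diagnosis) to "persistent
diagnosis with remittent symptoms", the stable symptoms-only and stable
previous-diagnosis pairs to their own patterns, and everything else to an
explicit `unclassified` label (never silently merged; a mapping with
`fallback=None` raises instead, naming the pair).

## Synthetic cohort generator

The generator emulates a two-wave adult questionnaire cohort top-down from
the latent structure the analysis assumes:

- **Covariates.** Age ~ Normal(56.7, 15.5) truncated to [17, 91];
  categorical and binary covariates drawn independently at configurable
  marginals (defaults are realistic adult general-population prevalences:
  52.7% female, 40.7% family history of asthma, 58.4% traffic exposure,
  19.4% current smokers, …).
- **Pattern.** A multinomial logit over the four longitudinal patterns
  with ex-asthma as reference. Default intercepts put the reference
  covariate profile at shares (27.2, 4.6, 44.0, 24.1)%; default covariate
  log odds ratios are realistic adjusted effect sizes (e.g. current
  smoking → persistent symptoms without diagnosis, OR 6.24). Age enters
  per year, centred at the cohort mean, so intercepts stay interpretable
  and zeroing all effects recovers the stated shares exactly.
- **Classes.** The pattern fixes the (baseline, follow-up) phenotype pair,
  deterministically by default; a distribution over pairs can be supplied
  to exercise the mapping's fallback path.
- **Indicators.** Attacks and wheeze are independent Bernoulli draws given
  class and wave. The two diagnosis indicators come from a single
  three-level draw (no diagnosis / previous / current) because they encode
  mutually exclusive answers to one question, so the pair (1, 1) can never
  occur; this requires ρ_prev + ρ_current ≤ 1 within each class and wave,
  validated at configuration time.
- **Reproducibility.** Every field draws from its own child RNG stream
  keyed by a stable hash of the field name, so generation is
  bit-reproducible given the seed and adding a covariate never perturbs
  the draws of existing fields.
- **Missingness.** Optional independent masking of each indicator cell at
  a configurable rate (default 0) to exercise the likelihood's
  marginalisation path.

What the generator does **not** emulate: covariate correlations (e.g.
smoking × COPD — real cohorts have them, defaults assume independence),
reporting/recall bias, loss to follow-up, interview-timing variability,
and within-class item dependence beyond the diagnosis constraint. Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to their violation in real
data.

Note one deliberate interaction: whenever a class gives positive
probability to *both* diagnosis levels, the three-level draw makes the two
diagnosis items negatively dependent within that class, which violates
local independence — exactly as a real single-question instrument would.
Fits to such cohorts (including the generator's defaults) are therefore a
mild misspecification study; BIC may prefer extra classes there, which is
the expected behaviour of BIC under local dependence, not a defect.

### Named scenarios

- `well_separated_config(n, seed)` — recovery studies. All covariate
  effects zero; pattern shares (27, 3, 25, 45)% give initial class
  probabilities (0.30, 0.45, 0.25) and transition rows (0.9, 0.1, 0) /
  (0, 1, 0) / (0, 0, 1); item profiles (0, .95, .95, .95) /
  (.95, 0, .05, .05) / (0, 0, .05, .95) so every class pair differs by
  ≥ 0.9 on at least two items and one diagnosis level is exactly 0 per
  class (making the panel an exact latent transition model). Under this
  scenario EM recovers δ, τ, ρ within ±0.03 elementwise in ≥ 18/20
  replicates at n = 2000, and BIC selects K = 3 at n = 1500.
- `smoking_recovery_config(n, seed)` — odds-ratio recovery. Only the
  smoking effects are active (current: 1.59/1.19/6.24, ex: 0.71/0.45/1.71
  vs ex-asthma); smoking is drawn uniformly over its three levels and the
  intercepts are solved so the expected pattern marginal is uniform — the
  allocation that minimises the Wald standard errors of the smoking
  coefficients at fixed n. This design choice matters: at n = 20 000 the
  six smoking log-OR standard errors are ≈ 0.05, so a ±10% odds-ratio
  check is informative, whereas under the cohort-default prevalences the
  rare remittent pattern (≈ 5%) pushes standard errors to 0.1–0.18 and no
  estimator could meet that tolerance reliably.

## Association stage

- **Contingency tables.** Pearson chi-square (no continuity correction)
  with expected counts and p-values from `scipy.stats.chi2_contingency`;
  the cell-level post-hoc is the adjusted standardized residual
  (O−E)/√(E(1−row/n)(1−col/n)), ≈ N(0,1) under independence, flagged at
  |r| > 1.96 (two-sided 0.05). Zero-margin rows/columns are excluded from
  the chi-square (computed on the reduced table, with a warning) and carry
  NaN residuals.
- **ANOVA.** Classical one-way decomposition via `scipy.stats.f_oneway`;
  a constant response returns F = 0, p = 1; all-singleton groups are an
  error (no within-group degrees of freedom).
- **Multinomial logistic regression.** Baseline-category logit fitted by
  Newton–Raphson on the full (p·(m−1))-dimensional system with
  step-halving, so the concave log-likelihood never decreases; convergence
  when the score norm < 10⁻⁶, at most 200 iterations. Wald standard errors
  from the inverse observed information; OR = exp(b), 95% CI
  = exp(b ± 1.96·SE). Rank-deficient designs raise with the aliased terms
  named; apparent separation (a coefficient diverging past ±30) returns
  `converged=False` with the offending term named. Categorical covariates
  expand against conventional reference levels (female, never-smokers,
  underweight/normal BMI, elementary education); age enters per year.
- **Variable retention.** "Only significant variables retained" is
  implemented as a single backward pass: a covariate is kept if any of its
  design columns has Wald p < 0.05 for any non-reference outcome; the rest
  are dropped together and the model refitted once. This is one reasonable
  reading of a procedure that admits several (order of removal and exact
  criterion being underdetermined); the full model is always reported
  alongside the reduced one.

## Pipeline and provenance

The four stages (simulate → fit → patterns → associate) run individually
or as `run-all`. A single master seed is hashed into independent per-stage
seeds, so stages rerun in isolation reproduce their outputs byte for byte;
every output file carries a leading comment with the seed, a configuration
hash, and the package version.

## Problem sizes

Recovery and selection studies use n = 1500–2000 with 20 replicates and
8–10 EM restarts; the odds-ratio recovery uses one cohort of n = 20 000;
oracle checks enumerate class sequences on panels with n ≤ 20, K ≤ 4,
T ≤ 3. These sizes make each study take seconds to a couple of minutes on
a single CPU while keeping every check statistically meaningful at its
stated tolerance.

## Known limitations

- Wald (not profile-likelihood) intervals; they can misbehave near
  separation, which is reported rather than corrected (no Firth penalty).
- The EM restarts guard against, but cannot rule out, local maxima for
  poorly separated classes; the BIC table records non-convergence per K.
- The generator's independence of covariates limits how realistic the
  association-stage simulations can be; effect-recovery checks are exact
  in the logit scale precisely because the generating model is the fitted
  model.
- Standard errors of the latent-model parameters are not computed (no
  observed-information inversion for δ, τ, ρ); inference downstream is on
  the association stage only, treating modal assignment as fixed.
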