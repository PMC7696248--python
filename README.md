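# phenolta

Latent transition analysis (LTA) of longitudinal asthma phenotypes in
two-wave questionnaire cohorts, with the downstream epidemiological
association stage.

## The problem

Adult asthma rarely behaves like a fixed yes/no condition: diagnoses are
reported and then "no longer had", symptoms remit and recur, and wheeze
occurs without any diagnosis at all. Epidemiological surveys capture this
with a handful of binary indicators — previous physician-diagnosed asthma,
current physician-diagnosed asthma, asthma attacks, and wheeze in the last
12 months — asked at a baseline interview and again about a year later.
`phenolta` implements the standard unsupervised workflow for such data:

1. **Latent transition model.** Each subject occupies one of *K* latent
   phenotype classes at each wave. With class sequence
   *(S₁, S₂)* and binary items *Y_{jt}*, the likelihood of a response
   vector is

   P(Y) = Σ_{s₁,s₂} δ_{s₁} τ_{s₁s₂} Π_{j,t} ρ_{s_t j t}^{Y_{jt}} (1−ρ_{s_t j t})^{1−Y_{jt}}

   where δ is the initial class distribution, τ the class transition
   matrix, and ρ the item-response probabilities (wave-specific by
   default). Estimation is by EM with an exact forward–backward E-step;
   missing items are marginalised (missing at random).
2. **Model selection.** Models for K = 1…K_max are compared by
   BIC = −2 log L + p log n, the lowest BIC wins, and ties go to the
   smaller K.
3. **Patterns.** Each subject is assigned, per wave, the class with the
   maximum posterior membership probability; the ordered pair of modal
   phenotypes is mapped (by a configurable table) to one of four
   longitudinal patterns: persistent diagnosis with persistent/incident
   symptoms, persistent diagnosis with remittent symptoms, persistent
   symptoms without diagnosis, and ex-asthma.
4. **Associations.** Patterns are cross-tabulated against host and
   environmental factors (chi-square with adjusted standardized residuals
   as the cell-level post-hoc, one-way ANOVA for continuous variables) and
   modelled by multinomial logistic regression with ex-asthma as the
   reference, reporting adjusted odds ratios with 95% Wald intervals.

A synthetic cohort generator produces data with exactly this latent
structure (plus realistic covariates and configurable effect sizes), so
the whole pipeline is testable end to end without access to any real
cohort. See `docs/methods.md` for modelling details and limitations.

## Worked example

```python
from phenolta import (EMOptions, assign_patterns, generate_cohort,
                      posterior_membership, select_model, transition_table,
                      well_separated_config)

cohort = generate_cohort(well_separated_config(n_subjects=2000, seed=7))
panel = cohort.manifest_panel()

fit, bic_table = select_model(panel, K_max=4, options=EMOptions(n_restarts=10, seed=1))
print(bic_table[["K", "log_likelihood", "bic"]].round(1).to_string(index=False))

member = posterior_membership(panel, fit.params)
print(transition_table(member).to_frame(percentages=True).round(1))
print(assign_patterns(member).to_frame().round(1))
```

prints

```
 K  log_likelihood     bic
 1        -10368.8 20798.4
 2         -6110.5 12365.5
 3         -4528.2  9299.7
 4         -4522.3  9401.8
               dx_symptoms  prev_dx  symptoms_only
dx_symptoms           89.6     10.4            0.0
prev_dx                0.0    100.0            0.0
symptoms_only          0.0      0.0          100.0
                           count  percent
persistent_dx_symptoms       571     28.6
persistent_dx_remittent       66      3.3
persistent_symptoms_no_dx    493     24.6
ex_asthma                    870     43.5
unclassified                   0      0.0
```

BIC correctly picks the generating K = 3; the transition table shows the
high wave-to-wave stability of the three phenotypes (rows are baseline
classes, entries are row percentages); and the pattern table counts each
modal phenotype pair. The generating scenario used here draws patterns at
(27/3/25/45)% — the fitted shares agree up to posterior assignment noise.

The same pipeline runs from the shell:

```sh
phenolta run-all --seed 1 --out results/demo --k-max 4
```

producing the cohort CSV, the model artifact with a BIC table and a
readable item-probability report, the assignment/transition/prevalence
tables, and the association reports (chi-square with flagged residuals,
ANOVA, and full + backward-reduced odds-ratio tables), all stamped with
the seed and configuration hash.

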