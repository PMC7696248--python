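"""Chi-square with adjusted residuals, ANOVA, multinomial logistic regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenolta import (
    CohortTable,
    GeneratorConfig,
    anova_oneway,
    backward_eliminate,
    chi2_with_residuals,
    fit_multinomial,
    generate_cohort,
    multinomial_logit,
)
from phenolta.cohort import zero_pattern_effects


def reference_chi2(O):
    """Independent textbook implementation: expected counts, Pearson X2,
    and adjusted standardized residuals, all from the explicit formulas."""
    O = np.asarray(O, dtype=float)
    n = O.sum()
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    E = row @ col / n
    chi2 = ((O - E) ** 2 / E).sum()
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = stats.chi2.sf(chi2, dof)
    resid = (O - E) / np.sqrt(E * (1 - row / n) * (1 - col / n))
    return chi2, dof, p, E, resid


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


def test_perfect_independence_gives_zero_chi2_and_residuals():
    res = chi2_with_residuals([[10, 10], [10, 10]])
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.adj_std_residuals, 0.0)
    assert res.dof == 1
    assert not res.significant.any()


def test_sleep_apnea_table_matches_hand_computed_oracle():
    """2x2 sleep-apnea-by-pattern table: chi-square, residuals and the
    unadjusted cross-product odds ratio all agree with explicit formulas."""
    O = [[25, 98], [3, 106]]
    res = chi2_with_residuals(O)
    chi2, dof, p, E, resid = reference_chi2(O)
    assert res.chi2 == pytest.approx(chi2, rel=1e-12)
    assert res.dof == dof
    assert res.p_value == pytest.approx(p, rel=1e-10)
    assert np.allclose(res.expected, E)
    assert np.allclose(res.adj_std_residuals, resid, atol=1e-12)
    # the cross-product ratio of this integer table
    odds_ratio = (25 * 106) / (98 * 3)
    assert odds_ratio == pytest.approx(9.01, abs=0.005)
    assert res.significant[0, 0]


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000), r=st.integers(2, 5), c=st.integers(2, 5))
def test_chi2_matches_textbook_formulas_on_random_tables(seed, r, c):
    rng = np.random.default_rng(seed)
    O = rng.integers(1, 40, size=(r, c))
    res = chi2_with_residuals(O)
    chi2, dof, p, E, resid = reference_chi2(O)
    assert res.chi2 == pytest.approx(chi2, rel=1e-10)
    assert res.dof == dof
    assert np.allclose(res.adj_std_residuals, resid, atol=1e-10)
    if r == 2:  # two-level margin: residuals are antisymmetric across rows
        assert np.allclose(res.adj_std_residuals[0], -res.adj_std_residuals[1], atol=1e-9)


def test_zero_margin_row_is_excluded_with_warning():
    O = [[10, 20], [0, 0], [30, 5]]
    with pytest.warns(UserWarning, match="zero-margin"):
        res = chi2_with_residuals(O)
    assert np.isnan(res.adj_std_residuals[1]).all()
    assert np.isfinite(res.chi2)
    assert res.dof == 1  # reduced 2x2


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def test_identical_groups_give_zero_f():
    res = anova_oneway([[1, 2, 3], [1, 2, 3]])
    assert res.F == pytest.approx(0.0, abs=1e-12)


def test_constant_values_give_f_zero_p_one():
    res = anova_oneway([[5.0, 5.0], [5.0, 5.0, 5.0]])
    assert res.F == 0.0 and res.p_value == 1.0


def test_all_singleton_groups_rejected():
    with pytest.raises(ValueError, match="degrees of freedom"):
        anova_oneway([[1.0], [2.0]])


def test_anova_matches_sum_of_squares_oracle(rng):
    groups = [rng.normal(loc=m, size=n) for m, n in [(0, 8), (0.5, 12), (1, 6), (0, 9)]]
    res = anova_oneway(groups)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    F = (ss_between / 3) / (ss_within / (len(allv) - 4))
    assert res.F == pytest.approx(F, rel=1e-10)
    assert res.p_value == pytest.approx(stats.f.sf(F, 3, len(allv) - 4), rel=1e-10)


# ---------------------------------------------------------------------------
# multinomial logistic regression
# ---------------------------------------------------------------------------


def _counts_cohort(counts):
    """Minimal cohort whose outcome has the given per-pattern counts."""
    labels = ["persistent_dx_symptoms", "persistent_dx_remittent",
              "persistent_symptoms_no_dx", "ex_asthma"]
    y = np.repeat(labels, counts)
    df = pd.DataFrame({"id": [f"S{i:06d}" for i in range(len(y))]})
    return df, y


def test_intercept_only_closed_form():
    """Intercepts equal the log count ratios against the reference group."""
    df, y = _counts_cohort([123, 21, 199, 109])
    X = np.ones((len(y), 1))
    levels = ["ex_asthma", "persistent_dx_symptoms", "persistent_dx_remittent",
              "persistent_symptoms_no_dx"]
    idx = {l: k for k, l in enumerate(levels)}
    fit = multinomial_logit(X, np.array([idx[v] for v in y]), ["intercept"], levels)
    assert fit.converged
    expect = np.log(np.array([123, 21, 199]) / 109)
    got = fit.coefficients.loc["intercept", levels[1:]].to_numpy(dtype=float)
    assert got == pytest.approx(expect, abs=1e-8)


def test_two_outcome_binary_covariate_equals_cross_product_ratio(rng):
    x = rng.integers(0, 2, 400)
    y = (rng.random(400) < 1 / (1 + np.exp(-(-0.4 + 0.9 * x)))).astype(int)
    tab = np.array([
        [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
        [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
    ])
    cross_product = tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0])
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    fit = multinomial_logit(X, y, ["intercept", "x"], ["ctrl", "case"])
    assert float(fit.odds_ratios.loc["x", "case"]) == pytest.approx(
        cross_product, abs=1e-8
    )


def test_collapsing_three_outcomes_to_two_matches_binary_logistic(rng):
    """Fitting the two-outcome subset of a 3-level outcome reproduces the
    binary logistic estimates (baseline-category equivalence)."""
    n = 600
    x = rng.normal(size=n)
    lin1, lin2 = 0.3 + 0.8 * x, -0.2 + 0.1 * x
    e = np.column_stack([np.ones(n), np.exp(lin1), np.exp(lin2)])
    probs = e / e.sum(axis=1, keepdims=True)
    u = rng.random(n)
    y = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)
    keep = y != 2
    X = np.column_stack([np.ones(keep.sum()), x[keep]])
    sub = multinomial_logit(X, y[keep], ["intercept", "x"], ["a", "b"])
    # independent binary logistic via statsmodels
    import statsmodels.api as sm

    ref = sm.Logit(y[keep], X).fit(disp=0)
    assert np.allclose(
        sub.coefficients["b"].to_numpy(dtype=float), ref.params, atol=1e-6
    )


def test_against_statsmodels_mnlogit(rng):
    import statsmodels.api as sm

    n = 500
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    y = rng.integers(0, 3, n)
    mine = multinomial_logit(X, y, ["c", "z", "b"], ["L0", "L1", "L2"])
    other = sm.MNLogit(y, X).fit(disp=0)
    assert np.abs(mine.coefficients.to_numpy() - np.asarray(other.params)).max() < 1e-5
    assert np.abs(
        mine.standard_errors.to_numpy()
        - np.asarray(other.bse).reshape(mine.standard_errors.shape, order="F")
    ).max() < 1e-5
    assert mine.log_likelihood == pytest.approx(other.llf, rel=1e-9)


def test_newton_ascent_and_gradient_at_convergence(rng):
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.integers(0, 3, n)
    fit = multinomial_logit(X, y, ["c", "z"], ["L0", "L1", "L2"])
    assert fit.converged
    assert (np.diff(fit.ll_trace) >= -1e-12).all()
    # recompute the score at the solution
    Y = np.zeros((n, 2))
    for k in (1, 2):
        Y[y == k, k - 1] = 1
    eta = X @ fit.coefficients.to_numpy()
    lse = np.logaddexp.reduce(np.column_stack([np.zeros(n), eta]), axis=1)
    G = X.T @ (Y - np.exp(eta - lse[:, None]))
    assert np.linalg.norm(G) < 1e-6


def test_separation_reported_not_silent():
    x = np.array([0.0] * 20 + [1.0] * 20)
    y = np.array([0] * 20 + [1] * 20)  # perfectly separated
    X = np.column_stack([np.ones(40), x])
    fit = multinomial_logit(X, y, ["intercept", "x"], ["a", "b"])
    assert not fit.converged
    assert "x" in fit.message


def test_rank_deficient_design_names_aliased_term():
    n = 50
    x = np.linspace(0, 1, n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(ValueError, match="rank deficient"):
        multinomial_logit(X, np.tile([0, 1], 25), ["c", "x", "x2"], ["a", "b"])


def test_wald_interval_coverage_over_replicates():
    """95% Wald CI covers the generating log-OR in 90-99% of 200 cohorts."""
    beta = np.log(2.0)
    rng = np.random.default_rng(123)
    covered = 0
    n = 2000
    for _ in range(200):
        x = rng.integers(0, 2, n).astype(float)
        p = 1 / (1 + np.exp(-(-0.5 + beta * x)))
        y = (rng.random(n) < p).astype(int)
        X = np.column_stack([np.ones(n), x])
        fit = multinomial_logit(X, y, ["c", "x"], ["a", "b"])
        lo = float(np.log(fit.ci_lower.loc["x", "b"]))
        hi = float(np.log(fit.ci_upper.loc["x", "b"]))
        covered += lo <= beta <= hi
    assert 0.90 <= covered / 200 <= 0.99


def test_backward_elimination_keeps_strong_drops_null():
    log_odds = zero_pattern_effects()
    log_odds["copd"] = tuple(np.log([4.0, 4.0, 4.0]))
    cohort = generate_cohort(
        GeneratorConfig(n_subjects=4000, seed=21, pattern_covariate_log_odds=log_odds)
    )
    y = cohort.data["true_pattern"].to_numpy()
    full, reduced, dropped = backward_eliminate(
        cohort, y, "ex_asthma", ["copd", "nasal_polyps"]
    )
    assert "nasal_polyps" in dropped
    assert "copd" in reduced.coefficients.index
    assert "nasal_polyps" not in reduced.coefficients.index


def test_fit_multinomial_expands_categoricals(rng):
    cohort = generate_cohort(GeneratorConfig(n_subjects=1500, seed=30))
    fit = fit_multinomial(
        cohort, cohort.data["true_pattern"].to_numpy(), "ex_asthma",
        ["age", "sex", "bmi_group", "smoking"],
    )
    for name in ("age", "sex_male", "bmi_group_overweight", "bmi_group_obese",
                 "smoking_ex", "smoking_current"):
        assert name in fit.coefficients.index
    # reference levels carry no columns
    assert "sex_female" not in fit.coefficients.index
    assert "smoking_never" not in fit.coefficients.index
    assert fit.reference == "ex_asthma"
    # OR/CI consistency with the coefficients
    assert np.allclose(
        fit.odds_ratios.to_numpy(), np.exp(fit.coefficients.to_numpy())
    )
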