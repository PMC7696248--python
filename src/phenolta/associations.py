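"""Association of longitudinal patterns with host and environmental factors.

Three inferential tools, matching standard epidemiological practice:

* Pearson chi-square on pattern-by-factor contingency tables, with
  adjusted standardized residuals as the cell-level post-hoc statistic
  for tables larger than 2 x 2:

      r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - row_i/n) (1 - col_j/n))

  approximately N(0, 1) under independence; |r| > 1.96 flags a cell at the
  two-sided 0.05 level.

* One-way ANOVA for continuous variables across patterns.

* Multinomial logistic regression of pattern membership (reference:
  ex-asthma) on covariates, fitted by Newton-Raphson with step-halving on
  the multinomial log-likelihood; Wald standard errors from the inverse
  observed information; odds ratios with 95% Wald intervals
  ``exp(b +/- 1.96 SE)``.  A single backward pass drops covariates whose
  Wald tests are non-significant for every non-reference pattern, then
  refits once ("only significant variables retained"); the full model is
  always available alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORY_LEVELS, CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "AnovaResult",
    "MultinomialFit",
    "chi2_with_residuals",
    "anova_oneway",
    "fit_multinomial",
    "multinomial_logit",
    "backward_eliminate",
    "build_design",
]

ALPHA = 0.05
Z_CRIT = float(stats.norm.ppf(1 - ALPHA / 2))  # 1.959964...

#: Reference level per categorical covariate in regression designs.
CATEGORY_REFERENCE = {
    "sex": "female",
    "bmi_group": "underweight_normal",
    "education": "elementary",
    "smoking": "never",
}


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    dof: int
    p_value: float
    adj_std_residuals: np.ndarray
    significant: np.ndarray  # |residual| > 1.96 at the 0.05 level
    notes: list


def chi2_with_residuals(observed) -> ContingencyResult:
    """Pearson chi-square with adjusted standardized residual post-hoc.

    ``observed`` is an r x c table of nonnegative integer counts (at least
    2 x 2).  Rows or columns with zero margin are excluded from the
    chi-square (computed on the reduced table, with a warning) and carry
    undefined (NaN) residuals.
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("observed must be at least a 2x2 table")
    if (O < 0).any() or not np.allclose(O, np.round(O)):
        raise ValueError("observed must contain nonnegative integer counts")
    notes: list[str] = []
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    n = O.sum()
    keep_r = row > 0
    keep_c = col > 0
    if not keep_r.all() or not keep_c.all():
        msg = "zero-margin rows/columns excluded from the chi-square"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    Osub = O[np.ix_(keep_r, keep_c)]
    if Osub.shape[0] < 2 or Osub.shape[1] < 2:
        raise ValueError("fewer than 2 nonzero rows/columns; chi-square undefined")
    res = stats.chi2_contingency(Osub, correction=False)
    expected = np.zeros_like(O)
    expected[np.ix_(keep_r, keep_c)] = res.expected_freq
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(
            expected * (1.0 - row[:, None] / n) * (1.0 - col[None, :] / n)
        )
        resid = np.where(denom > 0, (O - expected) / denom, np.nan)
    resid[~keep_r, :] = np.nan
    resid[:, ~keep_c] = np.nan
    with np.errstate(invalid="ignore"):
        sig = np.abs(resid) > Z_CRIT
    return ContingencyResult(
        observed=O.astype(int),
        expected=expected,
        chi2=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        adj_std_residuals=resid,
        significant=sig,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way ANOVA across groups of real values.

    Requires at least two groups, each non-empty, with at least one group
    of size >= 2 (otherwise the within-group degrees of freedom vanish).
    A panel of identical values yields F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must contain at least one value")
    sizes = np.array([len(g) for g in groups])
    n = int(sizes.sum())
    g = len(groups)
    if n - g < 1:
        raise ValueError("zero within-group degrees of freedom (all groups singletons)")
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        return AnovaResult(F=0.0, df_between=g - 1, df_within=n - g, p_value=1.0)
    res = stats.f_oneway(*groups)
    return AnovaResult(
        F=float(res.statistic),
        df_between=g - 1,
        df_within=n - g,
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------


@dataclass
class MultinomialFit:
    """Maximum-likelihood multinomial logit fit (baseline-category)."""

    outcome_levels: tuple[str, ...]   # reference first
    reference: str
    terms: tuple[str, ...]            # design column names, intercept first
    coefficients: pd.DataFrame        # terms x non-reference levels (log-odds)
    standard_errors: pd.DataFrame
    p_values: pd.DataFrame
    odds_ratios: pd.DataFrame
    ci_lower: pd.DataFrame
    ci_upper: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_iter: int
    n_obs: int
    ll_trace: np.ndarray
    message: str = ""

    def summary_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (outcome level, term)."""
        rows = []
        for level in self.coefficients.columns:
            for term in self.coefficients.index:
                rows.append(
                    {
                        "outcome": level,
                        "term": term,
                        "coef": self.coefficients.loc[term, level],
                        "se": self.standard_errors.loc[term, level],
                        "odds_ratio": self.odds_ratios.loc[term, level],
                        "ci_lower": self.ci_lower.loc[term, level],
                        "ci_upper": self.ci_upper.loc[term, level],
                        "p_value": self.p_values.loc[term, level],
                        "significant": self.p_values.loc[term, level] < ALPHA,
                    }
                )
        return pd.DataFrame(rows)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 10
    aliased = [names[i] for i in np.flatnonzero(diag < tol)]
    if aliased:
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")


def _mnlogit_ll(X, Y, B):
    eta = X @ B  # (n, m-1)
    lse = np.logaddexp.reduce(
        np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1), axis=1
    )
    return float((Y * eta).sum() - lse.sum()), eta, lse


def multinomial_logit(
    X: np.ndarray,
    y_index: np.ndarray,
    term_names: list[str],
    level_names: list[str],
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MultinomialFit:
    """Newton-Raphson fit of a baseline-category multinomial logit.

    ``y_index`` codes outcomes as 0..m-1 with 0 the reference level.  The
    log-likelihood is concave; Newton steps are safeguarded by step-halving
    so the log-likelihood never decreases.  Convergence is declared when the
    score (gradient) norm falls below ``tol``.  Diverging coefficients
    (quasi-complete separation) yield ``converged=False`` with the
    offending term named.
    """
    X = np.asarray(X, dtype=float)
    y_index = np.asarray(y_index, dtype=int)
    n, p = X.shape
    m = len(level_names)
    if m < 2:
        raise ValueError("need at least two outcome levels")
    _check_full_rank(X, term_names)
    Y = np.zeros((n, m - 1))
    for k in range(1, m):
        Y[y_index == k, k - 1] = 1.0

    B = np.zeros((p, m - 1))
    ll, eta, lse = _mnlogit_ll(X, Y, B)
    trace = [ll]
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        P = np.exp(eta - lse[:, None])  # (n, m-1)
        G = X.T @ (Y - P)               # (p, m-1) score
        gnorm = float(np.linalg.norm(G))
        if gnorm < tol:
            converged = True
            break
        # observed information: block (a, b) = X' diag(P_a (1[a=b] - P_b)) X
        H = np.empty((p * (m - 1), p * (m - 1)))
        for a in range(m - 1):
            for b in range(m - 1):
                wab = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                H[a * p : (a + 1) * p, b * p : (b + 1) * p] = X.T @ (X * wab[:, None])
        H = -H
        try:
            step = np.linalg.solve(-H, G.reshape(-1, order="F")).reshape(
                (p, m - 1), order="F"
            )
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        s = 1.0
        for _ in range(40):
            ll_new, eta_new, lse_new = _mnlogit_ll(X, Y, B + s * step)
            if ll_new >= ll - 1e-12:
                break
            s *= 0.5
        B = B + s * step
        ll, eta, lse = ll_new, eta_new, lse_new
        trace.append(ll)
        if np.abs(B).max() > 30:
            bad = np.unravel_index(np.abs(B).argmax(), B.shape)
            message = (
                f"apparent separation: coefficient for term '{term_names[bad[0]]}' "
                f"(outcome '{level_names[bad[1] + 1]}') is diverging"
            )
            break
    if not converged and not message:
        message = f"gradient norm {np.linalg.norm(X.T @ (Y - np.exp(eta - lse[:, None])))} after {it} iterations"

    # Wald covariance from the inverse observed information at the optimum
    P = np.exp(eta - lse[:, None])
    H = np.empty((p * (m - 1), p * (m - 1)))
    for a in range(m - 1):
        for b in range(m - 1):
            wab = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
            H[a * p : (a + 1) * p, b * p : (b + 1) * p] = X.T @ (X * wab[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape((p, m - 1), order="F")
    except np.linalg.LinAlgError:
        se = np.full((p, m - 1), np.nan)

    cols = level_names[1:]
    coef_df = pd.DataFrame(B, index=term_names, columns=cols)
    se_df = pd.DataFrame(se, index=term_names, columns=cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, B / se, np.nan)
    p_df = pd.DataFrame(2 * stats.norm.sf(np.abs(z)), index=term_names, columns=cols)
    with np.errstate(over="ignore"):  # diverged coefs map to inf ORs
        or_df = np.exp(coef_df)
        lo_df = np.exp(coef_df - Z_CRIT * se_df)
        hi_df = np.exp(coef_df + Z_CRIT * se_df)
    return MultinomialFit(
        outcome_levels=tuple(level_names),
        reference=level_names[0],
        terms=tuple(term_names),
        coefficients=coef_df,
        standard_errors=se_df,
        p_values=p_df,
        odds_ratios=or_df,
        ci_lower=lo_df,
        ci_upper=hi_df,
        log_likelihood=ll,
        converged=converged,
        n_iter=it,
        n_obs=n,
        ll_trace=np.array(trace),
        message=message,
    )


def build_design(
    data: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Expand covariates into a design matrix with an intercept.

    Categorical covariates are dummy-expanded against their conventional
    reference level (female sex, underweight/normal BMI, never-smokers,
    elementary education); binary covariates enter as 0/1; ``age`` enters
    per year.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["intercept"]
    for term in terms:
        if term in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[term]
            ref = CATEGORY_REFERENCE[term]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((data[term].to_numpy() == lev).astype(float))
                names.append(f"{term}_{lev}")
        elif term in data.columns:
            cols.append(data[term].to_numpy(dtype=float))
            names.append(term)
        else:
            raise KeyError(f"term '{term}' not found in cohort columns")
    return np.column_stack(cols), names


def fit_multinomial(
    cohort: CohortTable,
    outcome,
    reference: str,
    terms: list[str],
    **kwargs,
) -> MultinomialFit:
    """Multinomial logit of pattern membership on cohort covariates.

    ``outcome`` is an array of pattern labels aligned with the cohort rows;
    ``reference`` names the baseline pattern (conventionally ex-asthma).
    Non-reference outcome levels keep their order of first appearance in
    the pattern label set.
    """
    outcome = np.asarray(outcome, dtype=object)
    if len(outcome) != cohort.n:
        raise ValueError("outcome length must match the cohort")
    levels = list(pd.unique(outcome))
    if reference not in levels:
        raise ValueError(f"reference level '{reference}' absent from outcomes")
    ordered = [reference] + [l for l in levels if l != reference]
    level_index = {l: k for k, l in enumerate(ordered)}
    y_index = np.array([level_index[l] for l in outcome])
    X, names = build_design(cohort.data, terms)
    return multinomial_logit(X, y_index, names, ordered, **kwargs)


def backward_eliminate(
    cohort: CohortTable,
    outcome,
    reference: str,
    terms: list[str],
    alpha: float = ALPHA,
) -> tuple[MultinomialFit, MultinomialFit, list[str]]:
    """One backward pass: drop covariates non-significant everywhere, refit.

    A covariate is retained if any of its design columns has a Wald p-value
    below ``alpha`` for any non-reference outcome.  Returns (full fit,
    reduced fit, dropped covariates); if nothing is dropped the reduced fit
    is the full fit.
    """
    full = fit_multinomial(cohort, outcome, reference, terms)
    keep: list[str] = []
    dropped: list[str] = []
    for term in terms:
        prefix = (
            [f"{term}_{lev}" for lev in CATEGORY_LEVELS[term]]
            if term in CATEGORY_LEVELS
            else [term]
        )
        cols = [c for c in full.coefficients.index if c in prefix]
        pmin = full.p_values.loc[cols].to_numpy().min() if cols else 1.0
        (keep if pmin < alpha else dropped).append(term)
    if not dropped:
        return full, full, []
    if not keep:
        logger.warning("backward pass would drop every covariate; keeping full model")
        return full, full, []
    reduced = fit_multinomial(cohort, outcome, reference, keep)
    logger.info("backward elimination dropped: %s", dropped)
    return full, reduced, dropped
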