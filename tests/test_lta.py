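"""Latent transition model: likelihood, EM, BIC selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenolta import (
    EMOptions,
    LTAParameters,
    ManifestPanel,
    canonical_order,
    count_parameters,
    em_fit,
    log_likelihood,
    posteriors,
    select_model,
    well_separated_config,
    generate_cohort,
)
from phenolta.lta import DimensionError

from conftest import brute_force_loglik, random_panel, random_params


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------


def test_uniform_bernoulli_single_class():
    """With K=1 and every rho=0.5, each of the 8 cells contributes log 0.5."""
    panel = ManifestPanel(np.array([[[1, 0], [0, 1], [1, 1], [0, 0]]]))
    params = LTAParameters([1.0], [[1.0]], np.full((1, 4, 2), 0.5))
    assert log_likelihood(panel, params) == pytest.approx(8 * np.log(0.5), rel=1e-12)


def test_degenerate_fit_hits_clipping_floor():
    """rho exactly equal to a subject's 0/1 responses gives 8 log(1 - 1e-6)."""
    values = np.array([[[1, 0], [0, 1], [1, 1], [0, 0]]], dtype=float)
    params = LTAParameters([1.0], [[1.0]], values.copy())
    ll = log_likelihood(ManifestPanel(values), params)
    assert ll == pytest.approx(8 * np.log(1 - 1e-6), rel=1e-9)


@pytest.mark.parametrize("K,J,T,n,missing", [
    (3, 4, 2, 10, 0.0),
    (3, 4, 2, 10, 0.3),
    (4, 3, 3, 8, 0.2),
    (2, 1, 2, 6, 0.0),
])
def test_loglik_matches_brute_force_enumeration(rng, K, J, T, n, missing):
    panel = random_panel(rng, n, J, T, missing)
    params = random_params(rng, K, J, T)
    expected = brute_force_loglik(panel, params)
    assert log_likelihood(panel, params) == pytest.approx(expected, rel=1e-10)


def test_loglik_invariant_to_subject_order(rng):
    panel = random_panel(rng, 12, 4, 2)
    params = random_params(rng, 3, 4, 2)
    perm = rng.permutation(12)
    shuffled = ManifestPanel(panel.values[perm], panel.missing_mask[perm])
    assert log_likelihood(panel, params) == pytest.approx(
        log_likelihood(shuffled, params), rel=1e-12
    )


def test_all_missing_subject_contributes_zero(rng):
    params = random_params(rng, 2, 3, 2)
    values = rng.integers(0, 2, size=(2, 3, 2))
    mask = np.zeros_like(values, dtype=bool)
    mask[1] = True
    with pytest.warns(UserWarning, match="all items missing"):
        ll = log_likelihood(ManifestPanel(values, mask), params)
    base = log_likelihood(ManifestPanel(values[:1], mask[:1]), params)
    assert ll == pytest.approx(base, rel=1e-12)


def test_dimension_mismatch_raises(rng):
    panel = random_panel(rng, 5, 4, 2)
    params = random_params(rng, 2, 3, 2)
    with pytest.raises(DimensionError):
        log_likelihood(panel, params)


# ---------------------------------------------------------------------------
# parameter counting and BIC
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("K,J,T,constrained,expected", [
    (3, 4, 2, False, 32),
    (1, 4, 2, False, 8),
    (2, 1, 2, True, 5),
    (2, 4, 2, False, 19),
])
def test_count_parameters(K, J, T, constrained, expected):
    assert count_parameters(K, J, T, constrained) == expected


def test_bic_identity_as_stored(rng):
    panel = random_panel(rng, 50, 4, 2)
    fit = em_fit(panel, 2, EMOptions(n_restarts=3, seed=0))
    assert fit.bic == -2 * fit.log_likelihood + fit.n_parameters * np.log(panel.n)


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


def test_k1_closed_form(rng):
    """K=1 EM equals the closed form: rho = item means, delta=[1], tau=[[1]]."""
    panel = random_panel(rng, 40, 4, 2, missing_rate=0.2)
    fit = em_fit(panel, 1, EMOptions(n_restarts=1, seed=0))
    assert fit.params.delta == pytest.approx([1.0])
    assert fit.params.tau.ravel() == pytest.approx([1.0])
    obs = ~panel.missing_mask
    for j in range(4):
        for t in range(2):
            sel = obs[:, j, t]
            mean = panel.values[sel, j, t].mean()
            assert fit.params.rho[0, j, t] == pytest.approx(mean, abs=1e-12)


def test_em_bit_identical_given_seed(rng):
    panel = random_panel(rng, 100, 4, 2)
    opts = EMOptions(n_restarts=4, seed=7)
    a = em_fit(panel, 2, opts)
    b = em_fit(panel, 2, opts)
    assert a.log_likelihood == b.log_likelihood
    assert np.array_equal(a.params.delta, b.params.delta)
    assert np.array_equal(a.params.tau, b.params.tau)
    assert np.array_equal(a.params.rho, b.params.rho)
    assert a.iteration_count == b.iteration_count


def test_em_monotone_and_normalized(rng):
    cohort = generate_cohort(well_separated_config(500, seed=3))
    fit = em_fit(cohort.manifest_panel(), 3, EMOptions(n_restarts=3, seed=1))
    diffs = np.diff(fit.ll_trace)
    assert (diffs >= -1e-12 * np.abs(fit.ll_trace[:-1])).all()
    assert fit.params.delta.sum() == pytest.approx(1.0, abs=1e-12)
    assert fit.params.tau.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-12)


def test_em_weak_identifiability_warning():
    # 2 distinct response patterns cannot identify 3 classes
    values = np.zeros((10, 4, 2), dtype=int)
    values[5:] = 1
    with pytest.warns(UserWarning, match="distinct observed response"):
        em_fit(ManifestPanel(values), 3, EMOptions(n_restarts=1, seed=0, max_iter=50))


def test_canonical_order_undoes_relabelling(rng):
    params = LTAParameters(
        delta=[0.3, 0.45, 0.25],
        tau=[[0.9, 0.1, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
        rho=np.repeat(
            np.array([[0.0, 0.95, 0.95, 0.95],
                      [0.95, 0.0, 0.05, 0.05],
                      [0.0, 0.0, 0.05, 0.95]])[:, :, None], 2, axis=2),
    )
    ordered = canonical_order(params)
    perm = rng.permutation(3)
    relabelled = LTAParameters(
        delta=params.delta[perm],
        tau=params.tau[np.ix_(perm, perm)],
        rho=params.rho[perm],
    )
    back = canonical_order(relabelled)
    assert np.allclose(back.delta, ordered.delta)
    assert np.allclose(back.tau, ordered.tau)
    assert np.allclose(back.rho, ordered.rho)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    K=st.integers(1, 4),
    T=st.integers(2, 3),
    n=st.integers(1, 20),
)
def test_loglik_oracle_property(seed, K, T, n):
    """Forward algorithm equals class-sequence enumeration on small panels."""
    rng = np.random.default_rng(seed)
    J = int(rng.integers(1, 5))
    panel = random_panel(rng, n, J, T, missing_rate=0.15)
    params = random_params(rng, K, J, T)
    assert log_likelihood(panel, params) == pytest.approx(
        brute_force_loglik(panel, params), rel=1e-10
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def test_select_model_single_candidate(rng):
    panel = random_panel(rng, 60, 4, 2)
    fit, table = select_model(panel, 1, EMOptions(n_restarts=2, seed=0))
    assert fit.K == 1
    assert len(table) == 1
    assert table.loc[0, "K"] == 1


def test_select_model_prefers_smaller_k_on_ties(rng):
    panel = random_panel(rng, 60, 4, 2)
    fit, table = select_model(panel, 2, EMOptions(n_restarts=2, seed=0, max_iter=100))
    best = table.dropna(subset=["bic"]).sort_values(["bic", "K"]).iloc[0]
    assert fit.K == best["K"]
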