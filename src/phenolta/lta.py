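"""Latent transition model for binary indicators observed at multiple waves.

The model assumes each subject occupies one of ``K`` latent classes at every
wave.  Class membership at the first wave follows an initial distribution
``delta``; membership evolves between consecutive waves according to a
row-stochastic transition matrix ``tau``; and, conditional on class ``k`` at
wave ``t``, item ``j`` is an independent Bernoulli with success probability
``rho[k, j, t]``.  The observed-data likelihood of a subject's response
vector is therefore a sum over all ``K**T`` latent class sequences

    P(y_i) = sum_{s_1..s_T} delta[s_1] * prod_t tau[s_{t-1}, s_t]
                            * prod_{j,t} rho[s_t,j,t]^y * (1-rho[s_t,j,t])^(1-y)

with missing cells marginalised by dropping their Bernoulli factor
(missing-at-random).  Estimation is by EM with an exact E-step implemented
via the forward-backward recursions; the class posterior at each wave and
the pairwise transition posteriors are by-products reused for modal
assignment downstream.

Model choice across ``K`` uses the Bayesian Information Criterion,
``BIC = -2 log L + p log n``, with the smaller model preferred on ties
(parsimony).

Numerical conventions: probabilities are clipped to ``[1e-6, 1 - 1e-6]``
before logs, both when evaluating the likelihood and after every M-step, so
degenerate estimates cannot produce infinite logs.  Classes are reported in
a canonical order (see :func:`canonical_order`) so that repeated fits and
relabelled truths are directly comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Probability floor applied before logarithms and to M-step estimates.
PROB_EPS = 1e-6

#: Default manifest item labels (order matters for canonical class ordering).
ITEM_NAMES = ("prev_dx", "current_dx", "attacks", "wheeze")
WAVE_LABELS = ("baseline", "followup")

#: Canonical labels of the three cross-sectional phenotypes, in the order
#: produced by :func:`canonical_order` on well-separated fits:
#: asthma diagnosis with current symptoms, previous diagnosis only,
#: current symptoms without diagnosis.
CLASS_LABELS = ("dx_symptoms", "prev_dx", "symptoms_only")


class DimensionError(ValueError):
    """Raised when panel and parameter shapes disagree."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class ManifestPanel:
    """Binary item responses for ``n`` subjects, ``J`` items, ``T`` waves.

    Parameters
    ----------
    values
        ``(n, J, T)`` array of 0/1 responses.  Entries under the missing
        mask are ignored (any placeholder value is permitted there).
    missing_mask
        ``(n, J, T)`` boolean array, ``True`` where the response is missing.
    item_names, wave_labels
        Optional axis labels; defaulted for the four asthma indicators at
        two waves.
    """

    values: np.ndarray
    missing_mask: np.ndarray | None = None
    item_names: tuple[str, ...] | None = None
    wave_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionError(
                f"values must be (n, J, T), got shape {self.values.shape}"
            )
        n, J, T = self.values.shape
        if n < 1 or J < 1 or T < 2:
            raise DimensionError(f"need n >= 1, J >= 1, T >= 2, got {(n, J, T)}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise DimensionError("missing_mask shape must match values")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.isin(observed, (0, 1)).all():
            raise ValueError("non-missing entries must be 0 or 1")
        if self.item_names is None:
            self.item_names = (
                ITEM_NAMES if J == len(ITEM_NAMES) else tuple(f"item{j}" for j in range(J))
            )
        if self.wave_labels is None:
            self.wave_labels = (
                WAVE_LABELS if T == len(WAVE_LABELS) else tuple(f"wave{t}" for t in range(T))
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    @property
    def T(self) -> int:
        return self.values.shape[2]

    def response_codes(self) -> np.ndarray:
        """Encode each subject's responses as an ``(n, J*T)`` int matrix.

        0/1 for observed values, 2 for missing — used to collapse the panel
        to unique response patterns.
        """
        codes = np.where(self.missing_mask, 2, self.values.astype(np.int8))
        return codes.reshape(self.n, -1)


@dataclass
class LTAParameters:
    """Parameters of a ``K``-class latent transition model.

    ``delta`` is the initial class distribution, ``tau`` the class
    transition matrix (row = class at the earlier wave), and ``rho`` the
    ``(K, J, T)`` item-response probabilities.  ``constrained_rho`` records
    whether ``rho`` was constrained equal across waves during estimation
    (measurement invariance).
    """

    delta: np.ndarray
    tau: np.ndarray
    rho: np.ndarray
    constrained_rho: bool = False

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        K = self.delta.shape[0]
        if self.delta.ndim != 1:
            raise DimensionError("delta must be 1-D")
        if self.tau.shape != (K, K):
            raise DimensionError(f"tau must be ({K}, {K}), got {self.tau.shape}")
        if self.rho.ndim != 3 or self.rho.shape[0] != K:
            raise DimensionError(f"rho must be (K, J, T) with K={K}, got {self.rho.shape}")
        for name, arr in (("delta", self.delta), ("tau", self.tau), ("rho", self.rho)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if not np.isclose(self.delta.sum(), 1.0, atol=1e-8):
            raise ValueError("delta must sum to 1")
        if not np.allclose(self.tau.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("tau rows must sum to 1")
        if self.constrained_rho and not np.allclose(
            self.rho, self.rho[:, :, :1], atol=1e-10
        ):
            raise ValueError("constrained_rho requires rho identical across waves")

    @property
    def K(self) -> int:
        return self.delta.shape[0]

    @property
    def J(self) -> int:
        return self.rho.shape[1]

    @property
    def T(self) -> int:
        return self.rho.shape[2]


@dataclass
class EMOptions:
    """Fit options for :func:`em_fit`.

    tol
        Relative log-likelihood change below which EM is declared converged.
    n_restarts
        Number of random initialisations; the best final log-likelihood wins.
    order_items
        Item indices used (in priority order) to canonically order classes by
        descending baseline item-response probability.  Defaults to
        (current diagnosis, previous diagnosis, wheeze) for 4-item panels.
    """

    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 20
    seed: int = 0
    constrained_rho: bool = False
    order_items: tuple[int, ...] | None = None


@dataclass
class LTAFit:
    """Result of an EM fit at fixed ``K``."""

    params: LTAParameters
    log_likelihood: float
    bic: float
    n_parameters: int
    n_restarts_used: int
    converged: bool
    iteration_count: int
    seed: int
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def K(self) -> int:
        return self.params.K


# ---------------------------------------------------------------------------
# Likelihood machinery (forward-backward over class sequences)
# ---------------------------------------------------------------------------


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def _log_emissions(
    values: np.ndarray, mask: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """``(n, T, K)`` log P(observed items at wave t | class k)."""
    rho_c = _clip(rho)  # (K, J, T)
    log_r = np.log(rho_c)
    log_1mr = np.log1p(-rho_c)
    y = values.astype(float)
    obs = ~mask
    # contribution of item j at wave t for class k, zeroed where missing
    # einsum over j: (n,J,T) x (K,J,T) -> (n,T,K)
    logB = np.einsum("njt,kjt->ntk", y * obs, log_r) + np.einsum(
        "njt,kjt->ntk", (1.0 - y) * obs, log_1mr
    )
    return logB


def _forward(
    logB: np.ndarray, delta: np.ndarray, tau: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward pass.

    Returns ``alpha`` (n, T, K) scaled forward probabilities, ``shifts``
    (n, T) log-scale offsets, and per-subject log-likelihoods (n,).
    """
    n, T, K = logB.shape
    shifts = logB.max(axis=2)
    B = np.exp(logB - shifts[:, :, None])
    alpha = np.empty((n, T, K))
    loglik = shifts.sum(axis=1)
    a = _clip_nonneg(delta)[None, :] * B[:, 0, :]
    c = a.sum(axis=1)
    loglik += np.log(c)
    alpha[:, 0, :] = a / c[:, None]
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ tau) * B[:, t, :]
        c = a.sum(axis=1)
        loglik += np.log(c)
        alpha[:, t, :] = a / c[:, None]
    return alpha, shifts, loglik


def _clip_nonneg(p: np.ndarray) -> np.ndarray:
    # delta/tau entries may legitimately be ~0 after clipping in rho only;
    # floor them for log-free linear recursions to avoid exact-zero pivots.
    return np.clip(p, PROB_EPS, None)


def _backward(logB: np.ndarray, tau: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Scaled backward pass; returns ``beta`` (n, T, K) up to per-(i,t) scale."""
    n, T, K = logB.shape
    B = np.exp(logB - shifts[:, :, None])
    beta = np.empty((n, T, K))
    beta[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        b = (B[:, t + 1, :] * beta[:, t + 1, :]) @ tau.T
        beta[:, t, :] = b / b.max(axis=1, keepdims=True)
    return beta


def log_likelihood(panel: ManifestPanel, params: LTAParameters) -> float:
    """Observed-data log-likelihood of the panel under ``params``.

    Missing cells are marginalised (their Bernoulli factor is dropped);
    a subject with every cell missing contributes ``log 1 = 0`` and
    triggers a warning.  Equals brute-force enumeration over all ``K**T``
    class sequences.
    """
    _check_dims(panel, params)
    logB = _log_emissions(panel.values, panel.missing_mask, params.rho)
    if panel.missing_mask.all(axis=(1, 2)).any():
        warnings.warn(
            "panel contains subject(s) with all items missing; they "
            "contribute log(1) = 0 to the log-likelihood",
            stacklevel=2,
        )
    _, _, ll = _forward(logB, params.delta, params.tau)
    return float(ll.sum())


def _check_dims(panel: ManifestPanel, params: LTAParameters) -> None:
    if params.J != panel.J or params.T != panel.T:
        raise DimensionError(
            f"panel is (J={panel.J}, T={panel.T}) but parameters are "
            f"(J={params.J}, T={params.T})"
        )


def posteriors(
    panel: ManifestPanel, params: LTAParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """E-step quantities for the panel.

    Returns
    -------
    gamma : (n, T, K)
        Wave-marginal class posteriors ``P(class k at wave t | y_i)``.
    xi : (n, T-1, K, K)
        Pairwise transition posteriors between consecutive waves.
    loglik : (n,)
        Per-subject log-likelihood contributions.
    """
    _check_dims(panel, params)
    logB = _log_emissions(panel.values, panel.missing_mask, params.rho)
    return _posteriors_from_logB(logB, params.delta, params.tau)


def _posteriors_from_logB(
    logB: np.ndarray, delta: np.ndarray, tau: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, T, K = logB.shape
    alpha, shifts, loglik = _forward(logB, delta, tau)
    beta = _backward(logB, tau, shifts)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    B = np.exp(logB - shifts[:, :, None])
    xi = np.empty((n, T - 1, K, K))
    for t in range(T - 1):
        m = (
            alpha[:, t, :, None]
            * tau[None, :, :]
            * (B[:, t + 1, None, :] * beta[:, t + 1, None, :])
        )
        xi[:, t] = m / m.sum(axis=(1, 2), keepdims=True)
    return gamma, xi, loglik


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


def count_parameters(K: int, J: int, T: int, constrained_rho: bool = False) -> int:
    """Number of free parameters: (K-1) initial + K(K-1) transition + rho."""
    if min(K, J, T) < 1:
        raise ValueError("dimensions must be positive")
    rho_terms = K * J if constrained_rho else K * J * T
    return (K - 1) + K * (K - 1) + rho_terms


def canonical_order(
    params: LTAParameters, order_items: Sequence[int] | None = None
) -> LTAParameters:
    """Relabel classes into the package's canonical order.

    Classes are sorted by descending baseline item-response probability on a
    priority list of items — by default (current diagnosis, previous
    diagnosis, wheeze) for four-item panels, i.e. items ``(1, 0, 3)`` — so
    the asthma phenotypes order deterministically as (diagnosis with
    symptoms, previous diagnosis, symptoms only) regardless of the labels EM
    happened to converge to.
    """
    if order_items is None:
        order_items = (1, 0, 3) if params.J >= 4 else tuple(range(params.J))

    def _perm(t: int) -> np.ndarray:
        # primary keys: which items a class endorses (rho > 0.5), in priority
        # order; continuous rho values break ties.  Binarising first makes the
        # ordering robust to sampling noise in the small probabilities.
        items = list(order_items)
        keys = [-params.rho[:, j, t] for j in reversed(items)]
        keys += [-(params.rho[:, j, t] > 0.5).astype(float) for j in reversed(items)]
        return np.lexsort(keys)

    perm0 = _perm(0)
    if params.T == 2 and not params.constrained_rho:
        # With a single transition and wave-specific rho, the likelihood is
        # invariant to relabelling follow-up classes (permute tau columns
        # together with wave-2 rho), so each wave is ordered independently.
        perm1 = _perm(1)
        rho = np.stack([params.rho[perm0, :, 0], params.rho[perm1, :, 1]], axis=2)
        return LTAParameters(
            delta=params.delta[perm0],
            tau=params.tau[np.ix_(perm0, perm1)],
            rho=rho,
            constrained_rho=params.constrained_rho,
        )
    return LTAParameters(
        delta=params.delta[perm0],
        tau=params.tau[np.ix_(perm0, perm0)],
        rho=params.rho[perm0],
        constrained_rho=params.constrained_rho,
    )


def _init_params(
    rng: np.random.Generator, K: int, J: int, T: int, constrained_rho: bool
) -> LTAParameters:
    delta = rng.dirichlet(np.ones(K))
    tau = rng.dirichlet(np.ones(K), size=K)
    if constrained_rho:
        rho = np.repeat(rng.uniform(0.2, 0.8, size=(K, J, 1)), T, axis=2)
    else:
        rho = rng.uniform(0.2, 0.8, size=(K, J, T))
    return LTAParameters(delta, tau, rho, constrained_rho)


def _m_step(
    codes_values: np.ndarray,
    codes_obs: np.ndarray,
    w: np.ndarray,
    gamma: np.ndarray,
    xi: np.ndarray,
    constrained_rho: bool,
) -> LTAParameters:
    """Weighted M-step on collapsed unique response patterns."""
    wg = w[:, None, None] * gamma  # (u, T, K)
    delta = wg[:, 0, :].sum(axis=0)
    delta = _clip(delta / delta.sum())
    delta /= delta.sum()
    tau = (w[:, None, None, None] * xi).sum(axis=(0, 1))
    tau = _clip(tau / tau.sum(axis=1, keepdims=True))
    tau /= tau.sum(axis=1, keepdims=True)
    # rho[k, j, t] = weighted mean of observed y over subjects, class-weighted
    num = np.einsum("utk,ujt->kjt", wg, codes_values * codes_obs)
    den = np.einsum("utk,ujt->kjt", wg, codes_obs)
    if constrained_rho:
        num = num.sum(axis=2, keepdims=True)
        den = den.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
    if constrained_rho:
        rho = np.repeat(rho, codes_values.shape[2], axis=2)
    rho = _clip(rho)
    return LTAParameters(delta, tau, rho, constrained_rho)


def em_fit(panel: ManifestPanel, K: int, options: EMOptions | None = None) -> LTAFit:
    """Fit a ``K``-class latent transition model by multi-restart EM.

    The panel is first collapsed to its unique response patterns (with
    multiplicities), which makes each EM iteration O(#patterns · K²) rather
    than O(n · K²).  Each restart initialises ``delta`` and the rows of
    ``tau`` from flat Dirichlet draws and ``rho`` from Uniform(0.2, 0.8); the
    restart with the best final log-likelihood is kept and its classes are
    canonically reordered.  The observed-data log-likelihood is guaranteed
    non-decreasing across iterations (EM ascent); the recorded ``ll_trace``
    of the winning restart exposes this for verification.
    """
    if options is None:
        options = EMOptions()
    if K < 1:
        raise ValueError("K must be >= 1")
    n, J, T = panel.n, panel.J, panel.T

    codes = panel.response_codes()
    uniq, counts = np.unique(codes, axis=0, return_counts=True)
    if K > len(uniq):
        warnings.warn(
            f"K={K} exceeds the {len(uniq)} distinct observed response "
            "patterns; the model is weakly identified",
            stacklevel=2,
        )
    u_codes = uniq.reshape(-1, J, T)
    u_obs = (u_codes != 2).astype(float)
    u_values = np.where(u_codes == 2, 0, u_codes).astype(float)
    u_mask = u_codes == 2
    w = counts.astype(float)

    rng = np.random.default_rng(np.random.SeedSequence(options.seed))
    best: tuple[float, LTAParameters, np.ndarray, bool, int] | None = None
    for _ in range(options.n_restarts):
        params = _init_params(rng, K, J, T, options.constrained_rho)
        trace = []
        converged = False
        ll_old = -np.inf
        for it in range(options.max_iter):
            logB = _log_emissions(u_values, u_mask, params.rho)
            gamma, xi, ll_u = _posteriors_from_logB(logB, params.delta, params.tau)
            ll = float(w @ ll_u)
            trace.append(ll)
            logger.debug("EM K=%d iter=%d loglik=%.10f", K, it, ll)
            if it > 0:
                rel = (ll - ll_old) / max(abs(ll_old), 1.0)
                if rel < options.tol:
                    converged = True
                    break
            ll_old = ll
            params = _m_step(u_values, u_obs, w, gamma, xi, options.constrained_rho)
        if not converged:
            # hit max_iter after an M-step: evaluate the returned parameters
            logB = _log_emissions(u_values, u_mask, params.rho)
            _, _, ll_u = _posteriors_from_logB(logB, params.delta, params.tau)
            trace.append(float(w @ ll_u))
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], params, np.array(trace), converged, len(trace))

    assert best is not None
    ll_best, params, trace, converged, iters = best
    params = canonical_order(params, options.order_items)
    p = count_parameters(K, J, T, options.constrained_rho)
    bic = -2.0 * ll_best + p * np.log(n)
    return LTAFit(
        params=params,
        log_likelihood=ll_best,
        bic=float(bic),
        n_parameters=p,
        n_restarts_used=options.n_restarts,
        converged=converged,
        iteration_count=iters,
        seed=options.seed,
        ll_trace=trace,
    )


def select_model(
    panel: ManifestPanel, K_max: int, options: EMOptions | None = None
):
    """Fit K = 1..K_max and select the fit with the lowest BIC.

    Ties are broken toward smaller ``K`` (parsimony).  A failure at one
    ``K`` is recorded in the table and skipped; only total failure raises.

    Returns
    -------
    (LTAFit, pandas.DataFrame)
        The selected fit and a table with one row per candidate ``K``
        (log-likelihood, parameter count, BIC, convergence flag, error).
    """
    import pandas as pd

    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if options is None:
        options = EMOptions()
    rows = []
    fits: dict[int, LTAFit] = {}
    for K in range(1, K_max + 1):
        try:
            fit = em_fit(panel, K, options)
        except Exception as exc:  # recorded, not fatal
            logger.warning("fit at K=%d failed: %s", K, exc)
            rows.append(
                {"K": K, "log_likelihood": np.nan, "n_parameters": np.nan,
                 "bic": np.nan, "converged": False, "error": str(exc)}
            )
            continue
        fits[K] = fit
        rows.append(
            {"K": K, "log_likelihood": fit.log_likelihood,
             "n_parameters": fit.n_parameters, "bic": fit.bic,
             "converged": fit.converged, "error": ""}
        )
        logger.info("K=%d loglik=%.4f BIC=%.4f", K, fit.log_likelihood, fit.bic)
    if not fits:
        raise RuntimeError("every candidate K failed to fit")
    best_K = min(fits, key=lambda K: (fits[K].bic, K))
    return fits[best_K], pd.DataFrame(rows)


def params_to_dict(params: LTAParameters) -> dict:
    """JSON-serialisable representation at full precision."""
    return {
        "K": params.K,
        "delta": params.delta.tolist(),
        "tau": params.tau.tolist(),
        "rho": params.rho.tolist(),
        "constrained_rho": params.constrained_rho,
    }


def params_from_dict(d: dict) -> LTAParameters:
    return LTAParameters(
        delta=np.array(d["delta"]),
        tau=np.array(d["tau"]),
        rho=np.array(d["rho"]),
        constrained_rho=bool(d.get("constrained_rho", False)),
    )
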