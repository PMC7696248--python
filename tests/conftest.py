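"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's forward-backward machinery:
they enumerate every latent class sequence explicitly, so they stay valid
however the production code is vectorised.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phenolta import LTAParameters, ManifestPanel

CLIP = 1e-6


def brute_force_loglik(panel: ManifestPanel, params: LTAParameters) -> float:
    """Log-likelihood by explicit summation over all K**T class sequences."""
    rho = np.clip(params.rho, CLIP, 1 - CLIP)
    total = 0.0
    for i in range(panel.n):
        prob = 0.0
        for seq in itertools.product(range(params.K), repeat=panel.T):
            p = params.delta[seq[0]]
            for t in range(1, panel.T):
                p *= params.tau[seq[t - 1], seq[t]]
            for t in range(panel.T):
                for j in range(panel.J):
                    if panel.missing_mask[i, j, t]:
                        continue
                    r = rho[seq[t], j, t]
                    p *= r if panel.values[i, j, t] == 1 else 1 - r
            prob += p
        total += np.log(prob)
    return total


def brute_force_posteriors(panel: ManifestPanel, params: LTAParameters) -> np.ndarray:
    """Wave-marginal class posteriors by explicit Bayes over class sequences."""
    rho = np.clip(params.rho, CLIP, 1 - CLIP)
    K, T = params.K, panel.T
    gamma = np.zeros((panel.n, T, K))
    for i in range(panel.n):
        for seq in itertools.product(range(K), repeat=T):
            p = params.delta[seq[0]]
            for t in range(1, T):
                p *= params.tau[seq[t - 1], seq[t]]
            for t in range(T):
                for j in range(panel.J):
                    if panel.missing_mask[i, j, t]:
                        continue
                    r = rho[seq[t], j, t]
                    p *= r if panel.values[i, j, t] == 1 else 1 - r
            for t in range(T):
                gamma[i, t, seq[t]] += p
        gamma[i] /= gamma[i].sum(axis=1, keepdims=True)
    return gamma


def random_params(
    rng: np.random.Generator, K: int, J: int, T: int
) -> LTAParameters:
    return LTAParameters(
        delta=rng.dirichlet(np.ones(K)),
        tau=rng.dirichlet(np.ones(K), size=K),
        rho=rng.uniform(0.05, 0.95, size=(K, J, T)),
    )


def random_panel(
    rng: np.random.Generator, n: int, J: int, T: int, missing_rate: float = 0.0
) -> ManifestPanel:
    values = rng.integers(0, 2, size=(n, J, T))
    mask = rng.random((n, J, T)) < missing_rate
    # keep at least one observed cell per subject
    all_missing = mask.all(axis=(1, 2))
    mask[all_missing, 0, 0] = False
    return ManifestPanel(values, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
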