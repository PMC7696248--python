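"""Posterior class membership, modal assignment, transitions, and patterns.

After the latent transition model is fitted, each subject is assigned, at
each wave, the phenotype with the maximum posterior probability of class
membership (modal assignment; ties go to the lowest canonical class
index).  The ordered pair of modal phenotypes across the two waves is then
mapped to one of four longitudinal patterns.  The pair-to-pattern mapping
is data, not code: the grouping of rare off-diagonal transitions is
configurable, and pairs absent from the mapping fall back to an explicit
"unclassified" label (or raise, if no fallback is set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PATTERN_LABELS
from .lta import CLASS_LABELS, DimensionError, LTAParameters, ManifestPanel, posteriors

__all__ = [
    "PosteriorMembership",
    "PatternMapping",
    "PatternAssignment",
    "TransitionTable",
    "DEFAULT_PATTERN_MAPPING",
    "posterior_membership",
    "transition_table",
    "assign_patterns",
]

UNCLASSIFIED = "unclassified"

#: Default mapping of (baseline phenotype, follow-up phenotype) to
#: longitudinal pattern.  Persistent/incident symptomatic-diagnosis routes
#: all land in the first pattern; the improvement route (diagnosis with
#: symptoms -> previous diagnosis) defines the remittent pattern; stable
#: symptoms-only and stable previous-diagnosis define the remaining two.
#: Unlisted rare transitions fall back to "unclassified".
DEFAULT_PATTERN_MAPPING_TABLE: dict[tuple[str, str], str] = {
    ("dx_symptoms", "dx_symptoms"): "persistent_dx_symptoms",
    ("symptoms_only", "dx_symptoms"): "persistent_dx_symptoms",
    ("prev_dx", "dx_symptoms"): "persistent_dx_symptoms",
    ("dx_symptoms", "prev_dx"): "persistent_dx_remittent",
    ("symptoms_only", "symptoms_only"): "persistent_symptoms_no_dx",
    ("prev_dx", "prev_dx"): "ex_asthma",
}


@dataclass
class PatternMapping:
    """Configurable (baseline class, follow-up class) -> pattern table."""

    table: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MAPPING_TABLE)
    )
    fallback: str | None = UNCLASSIFIED

    def pattern_for(self, pair: tuple[str, str]) -> str:
        if pair in self.table:
            return self.table[pair]
        if self.fallback is None:
            raise KeyError(
                f"class pair {pair} has no configured pattern and no fallback"
            )
        return self.fallback

    @property
    def pattern_order(self) -> list[str]:
        order = [p for p in PATTERN_LABELS if p in set(self.table.values())]
        extras = [p for p in dict.fromkeys(self.table.values()) if p not in order]
        out = order + extras
        if self.fallback is not None:
            out.append(self.fallback)
        return out


DEFAULT_PATTERN_MAPPING = PatternMapping()


@dataclass
class PosteriorMembership:
    """Per-subject, per-wave posterior class probabilities and modal classes."""

    probs: np.ndarray  # (n, T, K)
    modal: np.ndarray  # (n, T)
    max_prob: np.ndarray  # (n, T)

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def T(self) -> int:
        return self.probs.shape[1]

    @property
    def K(self) -> int:
        return self.probs.shape[2]

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "PosteriorMembership":
        probs = np.asarray(probs, dtype=float)
        modal = probs.argmax(axis=2)  # argmax ties -> lowest index
        return cls(probs=probs, modal=modal, max_prob=probs.max(axis=2))

    @classmethod
    def from_modal(cls, modal: np.ndarray, K: int) -> "PosteriorMembership":
        """Degenerate membership with all posterior mass on given classes."""
        modal = np.asarray(modal, dtype=int)
        n, T = modal.shape
        probs = np.zeros((n, T, K))
        ii, tt = np.meshgrid(np.arange(n), np.arange(T), indexing="ij")
        probs[ii, tt, modal] = 1.0
        return cls(probs=probs, modal=modal, max_prob=np.ones((n, T)))


def posterior_membership(
    panel: ManifestPanel,
    params: LTAParameters,
    method: str = "wave_marginal",
) -> PosteriorMembership:
    """Posterior class membership per subject and wave.

    ``method="wave_marginal"`` (default) computes the per-wave marginal
    posterior P(class at wave t | full response vector) from the joint over
    class sequences and takes the modal class at each wave independently.
    ``method="sequence_modal"`` instead takes the jointly most probable
    class sequence (Viterbi decoding) and reads the per-wave classes off
    it; the reported probabilities remain the wave marginals.
    """
    gamma, _, _ = posteriors(panel, params)
    member = PosteriorMembership.from_probs(gamma)
    if method == "wave_marginal":
        return member
    if method == "sequence_modal":
        member.modal = _viterbi(panel, params)
        member.max_prob = np.take_along_axis(
            gamma, member.modal[:, :, None], axis=2
        )[:, :, 0]
        return member
    raise ValueError(f"unknown method '{method}'")


def _viterbi(panel: ManifestPanel, params: LTAParameters) -> np.ndarray:
    from .lta import _log_emissions

    logB = _log_emissions(panel.values, panel.missing_mask, params.rho)
    n, T, K = logB.shape
    log_delta = np.log(np.clip(params.delta, 1e-300, None))
    log_tau = np.log(np.clip(params.tau, 1e-300, None))
    score = log_delta[None, :] + logB[:, 0, :]
    back = np.zeros((n, T, K), dtype=int)
    for t in range(1, T):
        cand = score[:, :, None] + log_tau[None, :, :]  # (n, from, to)
        back[:, t] = cand.argmax(axis=1)
        score = cand.max(axis=1) + logB[:, t, :]
    path = np.empty((n, T), dtype=int)
    path[:, T - 1] = score.argmax(axis=1)
    for t in range(T - 2, -1, -1):
        path[:, t] = back[np.arange(n), t + 1, path[:, t + 1]]
    return path


@dataclass
class TransitionTable:
    """Cross-tabulation of modal classes between two waves."""

    counts: np.ndarray     # (K, K) ints
    row_pct: np.ndarray    # (K, K), NaN where the row total is zero
    class_labels: tuple[str, ...]

    def to_frame(self, percentages: bool = False) -> pd.DataFrame:
        mat = self.row_pct if percentages else self.counts
        return pd.DataFrame(mat, index=list(self.class_labels), columns=list(self.class_labels))


def transition_table(
    membership: PosteriorMembership, waves: tuple[int, int] | None = None
) -> TransitionTable:
    """K x K modal-class transition counts and row percentages.

    For panels with more than two waves a ``waves`` pair must name the two
    waves to cross-tabulate.  Rows with zero total carry NaN percentages.
    """
    if waves is None:
        if membership.T != 2:
            raise ValueError(
                f"membership has T={membership.T} waves; supply waves=(a, b) "
                "to select the pair to cross-tabulate"
            )
        waves = (0, 1)
    a, b = waves
    K = membership.K
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (membership.modal[:, a], membership.modal[:, b]), 1)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = np.where(totals > 0, 100.0 * counts / totals, np.nan)
    labels = (
        CLASS_LABELS if K == len(CLASS_LABELS) else tuple(f"class{k}" for k in range(K))
    )
    return TransitionTable(counts=counts, row_pct=row_pct, class_labels=labels)


@dataclass
class PatternAssignment:
    """Longitudinal pattern per subject, with counts and percentages."""

    labels: np.ndarray                 # (n,) pattern label per subject
    counts: "pd.Series"                # pattern -> count, in mapping order
    percentages: "pd.Series"           # pattern -> 100 * count / n

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "percent": self.percentages})


def assign_patterns(
    membership: PosteriorMembership,
    mapping: PatternMapping | None = None,
    class_labels: tuple[str, ...] | None = None,
) -> PatternAssignment:
    """Map each subject's modal (baseline, follow-up) pair to a pattern.

    A pure function of the modal pairs: identical pairs always receive the
    same label.  Patterns absent from the cohort keep a zero row in the
    counts so report tables have a stable shape.
    """
    if membership.T != 2:
        raise DimensionError("pattern assignment requires exactly two waves")
    if mapping is None:
        mapping = PatternMapping()
    if class_labels is None:
        class_labels = (
            CLASS_LABELS
            if membership.K == len(CLASS_LABELS)
            else tuple(f"class{k}" for k in range(membership.K))
        )
    pair_label: dict[tuple[int, int], str] = {}
    labels = np.empty(membership.n, dtype=object)
    for i, (a, b) in enumerate(membership.modal[:, :2]):
        key = (int(a), int(b))
        if key not in pair_label:
            pair_label[key] = mapping.pattern_for((class_labels[key[0]], class_labels[key[1]]))
        labels[i] = pair_label[key]
    order = mapping.pattern_order
    observed = [p for p in pd.unique(labels) if p not in order]
    order = order + observed
    counts = pd.Series(
        [int((labels == p).sum()) for p in order], index=order, name="count"
    )
    percentages = 100.0 * counts / max(len(labels), 1)
    percentages.name = "percent"
    return PatternAssignment(labels=labels, counts=counts, percentages=percentages)
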