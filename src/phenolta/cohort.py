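"""Synthetic cohort generator and cohort CSV round-trip.

Emulates the data structure of a two-wave telephone-questionnaire asthma
cohort: four binary asthma indicators (previous physician diagnosis,
current physician diagnosis, asthma attacks, wheeze) at baseline and a
12-month follow-up, plus host and environmental covariates.  Subjects are
generated top-down from the latent structure the downstream analysis
assumes:

1. covariates are drawn from configurable marginal distributions
   (independently — real covariate correlation is not emulated);
2. each subject's longitudinal pattern is drawn from a multinomial logit in
   the covariates, with "ex-asthma" as the reference pattern;
3. the pattern determines (deterministically by default) the latent
   phenotype pair (baseline class, follow-up class);
4. indicators are drawn independently given class and wave from
   item-response probabilities, except the two diagnosis items, which come
   from a single three-level draw (no diagnosis / previous / current)
   because they encode mutually exclusive answers to one question — so the
   pair can never be (1, 1).

Every field draws from its own child RNG stream keyed by a stable hash of
the field name, so adding a covariate never perturbs the draws of existing
fields and generation is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .lta import CLASS_LABELS, ITEM_NAMES, WAVE_LABELS, ManifestPanel

__all__ = [
    "GeneratorConfig",
    "CohortTable",
    "ConfigError",
    "CohortParseError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "PATTERN_LABELS",
    "REFERENCE_PATTERN",
]

#: Longitudinal pattern labels; the reference pattern is listed last.
PATTERN_LABELS = (
    "persistent_dx_symptoms",      # persistent diagnosis with persistent/incident symptoms
    "persistent_dx_remittent",     # persistent diagnosis with remittent symptoms
    "persistent_symptoms_no_dx",   # persistent symptoms without lifetime diagnosis
    "ex_asthma",                   # previous diagnosis at both waves
)
REFERENCE_PATTERN = "ex_asthma"

# Cross-sectional phenotype shares implied by the default pattern mix with
# deterministic class pairs: baseline ~(.318, .241, .440), close to the
# study-like (.285, .259, .456).
_DEFAULT_PATTERN_PROBS = (0.272, 0.046, 0.440, 0.241)

#: Default item-response probabilities rho[k, j, t]: class order
#: (dx_symptoms, prev_dx, symptoms_only), item order
#: (prev_dx, current_dx, attacks, wheeze), waves (baseline, followup).
DEFAULT_ITEM_RESPONSE_PROBS = np.array(
    [
        # dx_symptoms
        [[0.147, 0.115], [0.853, 0.861], [0.574, 0.504], [0.648, 0.738]],
        # prev_dx
        [[1.000, 0.992], [0.000, 0.008], [0.000, 0.031], [0.120, 0.092]],
        # symptoms_only
        [[0.000, 0.000], [0.000, 0.015], [0.102, 0.135], [0.302, 0.320]],
    ]
)

#: Default covariate marginals (binary prevalence or category distribution).
DEFAULT_COVARIATE_PREVALENCES: dict[str, float | dict[str, float]] = {
    "sex": {"male": 0.473, "female": 0.527},
    "bmi_group": {"underweight_normal": 0.490, "overweight": 0.353, "obese": 0.157},
    "education": {"elementary": 0.452, "high_school": 0.359, "university": 0.189},
    "family_history": 0.407,
    "allergic_rhinitis": 0.408,
    "gerd": 0.296,
    "sleep_apnea": 0.147,
    "recurrent_respiratory_infections": 0.135,
    "copd": 0.125,
    "nasal_polyps": 0.034,
    "smoking": {"never": 0.403, "ex": 0.403, "current": 0.194},
    "secondhand_smoke": 0.174,
    "traffic_exposure": 0.584,
}

#: Default pattern-covariate log odds ratios (term -> log-OR per non-reference
#: pattern, order persistent_dx_symptoms, persistent_dx_remittent,
#: persistent_symptoms_no_dx; reference ex_asthma).  Age enters per year,
#: centred at the cohort mean so the intercepts describe the
#: reference-profile subject.
DEFAULT_PATTERN_LOG_ODDS: dict[str, tuple[float, float, float]] = {
    "allergic_rhinitis": tuple(np.log([3.12, 3.38, 0.99])),
    "copd": tuple(np.log([4.76, 3.48, 1.32])),
    "sleep_apnea": tuple(np.log([5.99, 3.49, 5.32])),
    "traffic_exposure": tuple(np.log([1.86, 0.48, 1.31])),
    "smoking_current": tuple(np.log([1.59, 1.19, 6.24])),
    "smoking_ex": tuple(np.log([0.71, 0.45, 1.71])),
    "secondhand_smoke": tuple(np.log([2.64, 0.93, 3.28])),
    "age_centered": tuple(np.log([1.02, 0.98, 1.05])),
    "sex_male": tuple(np.log([0.84, 1.49, 0.84])),
    "bmi_obese": tuple(np.log([1.46, 0.63, 1.79])),
    "bmi_overweight": tuple(np.log([1.77, 4.58, 2.37])),
    "family_history": tuple(np.log([2.15, 2.60, 0.91])),
}

#: Deterministic (baseline class, follow-up class) pair per pattern.
DEFAULT_CLASS_SEQUENCE: dict[str, tuple[str, str] | dict[tuple[str, str], float]] = {
    "persistent_dx_symptoms": ("dx_symptoms", "dx_symptoms"),
    "persistent_dx_remittent": ("dx_symptoms", "prev_dx"),
    "persistent_symptoms_no_dx": ("symptoms_only", "symptoms_only"),
    "ex_asthma": ("prev_dx", "prev_dx"),
}

INDICATOR_COLUMNS = tuple(f"{item}_{wave}" for wave in WAVE_LABELS for item in ITEM_NAMES)
CATEGORY_LEVELS = {
    "sex": ("male", "female"),
    "bmi_group": ("underweight_normal", "overweight", "obese"),
    "education": ("elementary", "high_school", "university"),
    "smoking": ("never", "ex", "current"),
}
BINARY_COVARIATES = (
    "family_history", "allergic_rhinitis", "gerd", "sleep_apnea",
    "recurrent_respiratory_infections", "copd", "nasal_polyps",
    "secondhand_smoke", "traffic_exposure",
)
COLUMN_ORDER = (
    ("id", "age", "sex", "bmi_group", "education")
    + BINARY_COVARIATES[:7]
    + ("smoking",)
    + BINARY_COVARIATES[7:]
    + INDICATOR_COLUMNS
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


class CohortParseError(ValueError):
    """Malformed cohort CSV."""


def _default_intercepts() -> tuple[float, ...]:
    p = _DEFAULT_PATTERN_PROBS
    ref = p[-1]
    return tuple(math.log(pk / ref) for pk in p[:-1])


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reflect a realistic two-wave adult asthma cohort: pattern
    shares (27.2 / 4.6 / 44.0 / 24.1 %) at the reference covariate profile,
    covariate prevalences of a general-population sample aged 17-91, and
    adjusted odds-ratio effect sizes on the pattern logits.
    """

    n_subjects: int = 452
    seed: int = 0
    pattern_logit_intercepts: tuple[float, ...] = field(default_factory=_default_intercepts)
    pattern_covariate_log_odds: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_LOG_ODDS)
    )
    covariate_prevalences: dict[str, float | dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    class_sequence_by_pattern: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SEQUENCE)
    )
    item_response_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_ITEM_RESPONSE_PROBS.copy()
    )
    age_mean: float = 56.7
    age_sd: float = 15.5
    age_range: tuple[float, float] = (17.0, 91.0)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.item_response_probs = np.asarray(self.item_response_probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        n_nonref = len(PATTERN_LABELS) - 1
        if len(self.pattern_logit_intercepts) != n_nonref:
            raise ConfigError(
                f"pattern_logit_intercepts must have length {n_nonref}"
            )
        for term, betas in self.pattern_covariate_log_odds.items():
            if len(betas) != n_nonref:
                raise ConfigError(f"log-odds row for '{term}' must have length {n_nonref}")
        for name, spec in self.covariate_prevalences.items():
            if isinstance(spec, dict):
                probs = np.array(list(spec.values()), dtype=float)
                if ((probs < 0) | (probs > 1)).any():
                    raise ConfigError(f"distribution for '{name}' has probability outside [0, 1]")
                if not math.isclose(probs.sum(), 1.0, abs_tol=1e-8):
                    raise ConfigError(f"distribution for '{name}' must sum to 1")
            else:
                if not 0.0 <= float(spec) <= 1.0:
                    raise ConfigError(f"prevalence for '{name}' outside [0, 1]")
        rho = self.item_response_probs
        if rho.ndim != 3 or rho.shape[1] != len(ITEM_NAMES) or rho.shape[2] != len(WAVE_LABELS):
            raise ConfigError(
                f"item_response_probs must be (K, {len(ITEM_NAMES)}, {len(WAVE_LABELS)})"
            )
        if ((rho < 0) | (rho > 1)).any():
            raise ConfigError("item_response_probs outside [0, 1]")
        # diagnosis answers are mutually exclusive levels of one question
        if (rho[:, 0, :] + rho[:, 1, :] > 1.0 + 1e-9).any():
            raise ConfigError(
                "previous-diagnosis and current-diagnosis probabilities must "
                "sum to <= 1 within each class and wave"
            )
        for pat in PATTERN_LABELS:
            if pat not in self.class_sequence_by_pattern:
                raise ConfigError(f"pattern '{pat}' missing from class_sequence_by_pattern")
            spec = self.class_sequence_by_pattern[pat]
            pairs = [spec] if isinstance(spec, tuple) else list(spec)
            if not pairs:
                raise ConfigError(f"pattern '{pat}' maps to no class pair")
            for pair in pairs:
                if len(pair) != 2 or any(c not in CLASS_LABELS for c in pair):
                    raise ConfigError(f"invalid class pair {pair} for pattern '{pat}'")
            if isinstance(spec, dict):
                tot = sum(spec.values())
                if not math.isclose(tot, 1.0, abs_tol=1e-8):
                    raise ConfigError(f"class-pair distribution for '{pat}' must sum to 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate outside [0, 1]")


@dataclass
class CohortTable:
    """Subject-level cohort: covariates, two-wave indicators, optional truth.

    Thin wrapper around a :class:`pandas.DataFrame` with the fixed column
    layout of the cohort CSV.  ``true_pattern`` is present only for
    simulated cohorts.
    """

    data: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        if list(self.data.columns) != list(other.data.columns):
            return False
        try:
            pd.testing.assert_frame_equal(
                self.data.reset_index(drop=True),
                other.data.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True

    def manifest_panel(self) -> ManifestPanel:
        """Extract the (n, 4, 2) indicator panel with its missingness mask."""
        if self.n == 0:
            raise ValueError("cannot build a manifest panel from an empty cohort")
        values = np.zeros((self.n, len(ITEM_NAMES), len(WAVE_LABELS)))
        mask = np.zeros_like(values, dtype=bool)
        for t, wave in enumerate(WAVE_LABELS):
            for j, item in enumerate(ITEM_NAMES):
                col = self.data[f"{item}_{wave}"].to_numpy(dtype=float)
                miss = np.isnan(col)
                mask[:, j, t] = miss
                values[:, j, t] = np.where(miss, 0, col)
        return ManifestPanel(values, mask, ITEM_NAMES, WAVE_LABELS)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _field_rng(seed: int, name: str) -> np.random.Generator:
    # stable per-field stream: adding fields never perturbs existing ones
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(name.encode()))))


def _draw_categorical(rng, levels, probs, n):
    u = rng.random(n)
    edges = np.cumsum(probs)
    idx = np.searchsorted(edges, u, side="right")
    idx = np.minimum(idx, len(levels) - 1)
    return np.asarray(levels, dtype=object)[idx]


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a synthetic cohort under ``config``; deterministic in the seed."""
    config.validate()
    n = config.n_subjects
    columns = list(COLUMN_ORDER) + ["true_pattern"]
    if n == 0:
        return CohortTable(pd.DataFrame({c: pd.Series(dtype=object) for c in columns}))
    seed = config.seed

    data: dict[str, np.ndarray] = {}
    data["id"] = np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    u_age = _field_rng(seed, "age").random(n)
    age = stats.truncnorm.ppf(u_age, a, b, loc=config.age_mean, scale=config.age_sd)
    data["age"] = np.round(age, 1)

    for name, spec in config.covariate_prevalences.items():
        rng = _field_rng(seed, name)
        if isinstance(spec, dict):
            data[name] = _draw_categorical(
                rng, list(spec.keys()), np.array(list(spec.values()), dtype=float), n
            )
        else:
            data[name] = (rng.random(n) < float(spec)).astype(int)

    # pattern ~ multinomial logit (reference pattern carries linear predictor 0)
    eta = np.tile(np.asarray(config.pattern_logit_intercepts, dtype=float), (n, 1))
    term_values = _resolve_terms(data, config)
    for term, betas in config.pattern_covariate_log_odds.items():
        eta += term_values[term][:, None] * np.asarray(betas, dtype=float)[None, :]
    exp_eta = np.exp(np.column_stack([eta, np.zeros(n)]))
    probs = exp_eta / exp_eta.sum(axis=1, keepdims=True)
    u = _field_rng(seed, "pattern").random(n)
    pat_idx = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
    patterns = np.asarray(PATTERN_LABELS, dtype=object)[pat_idx]
    data["true_pattern"] = patterns

    # class pair per pattern
    base_cls = np.empty(n, dtype=int)
    fup_cls = np.empty(n, dtype=int)
    u_pair = _field_rng(seed, "class_pair").random(n)
    cls_index = {c: k for k, c in enumerate(CLASS_LABELS)}
    for pat in PATTERN_LABELS:
        sel = patterns == pat
        if not sel.any():
            continue
        spec = config.class_sequence_by_pattern[pat]
        if isinstance(spec, tuple):
            base_cls[sel] = cls_index[spec[0]]
            fup_cls[sel] = cls_index[spec[1]]
        else:
            pairs = list(spec.keys())
            edges = np.cumsum(np.array([spec[p] for p in pairs], dtype=float))
            choice = np.minimum(
                (u_pair[sel][:, None] >= edges[None, :]).sum(axis=1), len(pairs) - 1
            )
            base_cls[sel] = np.array([cls_index[pairs[c][0]] for c in choice])
            fup_cls[sel] = np.array([cls_index[pairs[c][1]] for c in choice])

    rho = config.item_response_probs
    cls_by_wave = (base_cls, fup_cls)
    for t, wave in enumerate(WAVE_LABELS):
        k = cls_by_wave[t]
        # single 3-level draw resolves the two mutually exclusive diagnosis items
        p_prev = rho[k, 0, t]
        p_cur = rho[k, 1, t]
        u_dx = _field_rng(seed, f"diagnosis_{wave}").random(n)
        prev = (u_dx < p_prev).astype(int)
        cur = ((u_dx >= p_prev) & (u_dx < p_prev + p_cur)).astype(int)
        data[f"prev_dx_{wave}"] = prev
        data[f"current_dx_{wave}"] = cur
        for j, item in ((2, "attacks"), (3, "wheeze")):
            u_it = _field_rng(seed, f"{item}_{wave}").random(n)
            data[f"{item}_{wave}"] = (u_it < rho[k, j, t]).astype(int)

    df = pd.DataFrame({c: data[c] for c in columns})
    if config.missing_rate > 0:
        u_miss = _field_rng(seed, "missingness").random((n, len(INDICATOR_COLUMNS)))
        for c_idx, col in enumerate(INDICATOR_COLUMNS):
            vals = df[col].astype(float)
            vals[u_miss[:, c_idx] < config.missing_rate] = np.nan
            df[col] = vals
    return CohortTable(df)


def _resolve_terms(data: dict, config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Numeric value of each logit term per subject."""
    out: dict[str, np.ndarray] = {}
    for term in config.pattern_covariate_log_odds:
        if term == "age_centered":
            out[term] = np.asarray(data["age"], dtype=float) - config.age_mean
        elif term == "sex_male":
            out[term] = (data["sex"] == "male").astype(float)
        elif term.startswith("smoking_"):
            out[term] = (data["smoking"] == term.removeprefix("smoking_")).astype(float)
        elif term.startswith("bmi_"):
            out[term] = (data["bmi_group"] == term.removeprefix("bmi_")).astype(float)
        elif term in data:
            out[term] = np.asarray(data[term], dtype=float)
        else:
            raise ConfigError(f"logit term '{term}' does not match any covariate")
    return out


# ---------------------------------------------------------------------------
# Named simulation scenarios
# ---------------------------------------------------------------------------


def zero_pattern_effects() -> dict[str, tuple[float, float, float]]:
    """Log-odds dictionary with every covariate effect set to zero."""
    return {k: (0.0, 0.0, 0.0) for k in DEFAULT_PATTERN_LOG_ODDS}


#: Item-response truth of the well-separated recovery scenario.  Each pair
#: of classes differs by >= 0.9 on at least two items, and per class at most
#: one of the two diagnosis levels has positive probability, so the
#: mutual-exclusivity draw leaves the items conditionally independent and
#: the generated panel is an exact latent transition model.
WELL_SEPARATED_RHO = np.repeat(
    np.array(
        [
            [0.00, 0.95, 0.95, 0.95],   # dx_symptoms
            [0.95, 0.00, 0.05, 0.05],   # prev_dx
            [0.00, 0.00, 0.05, 0.95],   # symptoms_only
        ]
    )[:, :, None],
    2,
    axis=2,
)
_WS_PATTERN_PROBS = (0.27, 0.03, 0.25, 0.45)
#: Implied latent truth of the scenario (classes in canonical order).
WELL_SEPARATED_DELTA = np.array([0.30, 0.45, 0.25])
WELL_SEPARATED_TAU = np.array([[0.9, 0.1, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


def well_separated_config(n_subjects: int, seed: int) -> GeneratorConfig:
    """Recovery-study scenario: well-separated K=3 truth, no covariate effects.

    Pattern probabilities (0.27, 0.03, 0.25, 0.45) with the deterministic
    class pairs give initial class probabilities (0.30, 0.45, 0.25) and a
    transition matrix with rows (0.9, 0.1, 0) / (0, 1, 0) / (0, 0, 1).
    """
    icpt = tuple(
        math.log(p / _WS_PATTERN_PROBS[-1]) for p in _WS_PATTERN_PROBS[:-1]
    )
    return GeneratorConfig(
        n_subjects=n_subjects,
        seed=seed,
        pattern_logit_intercepts=icpt,
        pattern_covariate_log_odds=zero_pattern_effects(),
        item_response_probs=WELL_SEPARATED_RHO.copy(),
    )


#: Intercepts solved (once, numerically) so that with smoking uniform over
#: its three levels and the smoking log-ORs below, the expected pattern
#: marginal is uniform — the allocation that maximises precision of the
#: smoking odds-ratio estimates at fixed n.
_SMOKING_SCENARIO_INTERCEPTS = (0.012113, 0.230507, -0.852937)


def smoking_recovery_config(n_subjects: int, seed: int) -> GeneratorConfig:
    """Odds-ratio recovery scenario: only the smoking effects are active.

    Generator truth keeps the default smoking log odds ratios
    (current: 1.59 / 1.19 / 6.24; ex: 0.71 / 0.45 / 1.71 against the
    ex-asthma reference) and zeroes every other covariate effect; smoking
    is drawn uniformly over never/ex/current so each exposure cell is as
    large as possible.
    """
    log_odds = zero_pattern_effects()
    log_odds["smoking_current"] = DEFAULT_PATTERN_LOG_ODDS["smoking_current"]
    log_odds["smoking_ex"] = DEFAULT_PATTERN_LOG_ODDS["smoking_ex"]
    prevalences = dict(DEFAULT_COVARIATE_PREVALENCES)
    prevalences["smoking"] = {"never": 1 / 3, "ex": 1 / 3, "current": 1 / 3}
    return GeneratorConfig(
        n_subjects=n_subjects,
        seed=seed,
        pattern_logit_intercepts=_SMOKING_SCENARIO_INTERCEPTS,
        pattern_covariate_log_odds=log_odds,
        covariate_prevalences=prevalences,
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortTable, path, header_comment: str | None = None) -> None:
    """Write the cohort as UTF-8 comma-delimited CSV.

    Binary fields are written as 0/1, missing indicator cells as empty
    strings.  An optional provenance comment (lines starting with ``#``)
    precedes the header; readers skip such lines.
    """
    path = Path(path)
    df = cohort.data.copy()
    for col in INDICATOR_COLUMNS:
        if col in df.columns and len(df):
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else str(int(v)), na_action=None
            )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV, validating categories and invariants row by row.

    Raises :class:`CohortParseError` naming the first offending data row
    (1-based, excluding header/comments) on malformed values, unknown
    category levels, duplicate ids, or violation of the diagnosis
    mutual-exclusivity invariant.  Empty indicator cells become missing
    values; the subject is retained.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMN_ORDER if c not in df.columns]
    if missing_cols:
        raise CohortParseError(f"cohort file lacks required columns: {missing_cols}")
    n = len(df)
    if n == 0:
        return CohortTable(pd.DataFrame({c: pd.Series(dtype=object) for c in df.columns}))

    def _bad_row(mask: np.ndarray) -> int:
        return int(np.flatnonzero(mask)[0]) + 1

    ids = df["id"].to_numpy()
    dup = pd.Series(ids).duplicated().to_numpy()
    if dup.any():
        raise CohortParseError(
            f"row {_bad_row(dup)}: duplicate subject id '{ids[_bad_row(dup) - 1]}'"
        )
    out = pd.DataFrame(index=df.index)
    out["id"] = ids
    try:
        out["age"] = df["age"].astype(float)
    except ValueError as exc:
        raise CohortParseError(f"malformed age value: {exc}") from None
    for col, levels in CATEGORY_LEVELS.items():
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, levels)
        if bad.any():
            r = _bad_row(bad)
            raise CohortParseError(
                f"row {r}: unknown level '{vals[r - 1]}' for '{col}' (expected {levels})"
            )
        out[col] = vals
    for col in BINARY_COVARIATES:
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, ("0", "1"))
        if bad.any():
            r = _bad_row(bad)
            raise CohortParseError(f"row {r}: binary field '{col}' must be 0/1, got '{vals[r - 1]}'")
        out[col] = vals.astype(int)
    for col in INDICATOR_COLUMNS:
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, ("0", "1", ""))
        if bad.any():
            r = _bad_row(bad)
            raise CohortParseError(
                f"row {r}: indicator '{col}' must be 0, 1 or empty, got '{vals[r - 1]}'"
            )
        out[col] = np.where(vals == "", np.nan, np.where(vals == "1", 1.0, 0.0))
    for wave in WAVE_LABELS:
        both = (out[f"prev_dx_{wave}"] == 1) & (out[f"current_dx_{wave}"] == 1)
        if both.any():
            r = _bad_row(both.to_numpy())
            raise CohortParseError(
                f"row {r}: previous and current diagnosis both 1 at wave "
                f"'{wave}' — they encode mutually exclusive answers to a "
                "single question"
            )
    if "true_pattern" in df.columns:
        out["true_pattern"] = df["true_pattern"].replace("", np.nan).to_numpy()
    out = out[[c for c in df.columns if c in out.columns]]
    return CohortTable(out)
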