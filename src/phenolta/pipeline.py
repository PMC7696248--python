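"""Pipeline driver: configuration, provenance, and the four analysis stages.

Stages mirror how the analysis runs on a real cohort: simulate (or supply)
a cohort CSV, fit the latent transition model across a range of class
numbers and keep the lowest-BIC model, derive modal phenotypes and
longitudinal patterns, then run the association stage.  A single master
seed is split into independent per-stage seeds so any stage can be rerun
in isolation and reproduce its outputs byte for byte.  Every output file
embeds the seed and a hash of the configuration in a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    GeneratorConfig,
    PATTERN_LABELS,
    REFERENCE_PATTERN,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .lta import (
    CLASS_LABELS,
    EMOptions,
    ITEM_NAMES,
    WAVE_LABELS,
    params_from_dict,
    params_to_dict,
    select_model,
)
from .patterns import (
    PatternMapping,
    assign_patterns,
    posterior_membership,
    transition_table,
)
from .associations import anova_oneway, backward_eliminate, chi2_with_residuals

logger = logging.getLogger(__name__)

DEFAULT_CATEGORICAL_VARS = [
    "sex", "bmi_group", "education", "family_history", "allergic_rhinitis",
    "gerd", "sleep_apnea", "recurrent_respiratory_infections", "copd",
    "nasal_polyps", "smoking", "secondhand_smoke", "traffic_exposure",
]
DEFAULT_CONTINUOUS_VARS = ["age"]
DEFAULT_REGRESSION_TERMS = [
    "allergic_rhinitis", "copd", "sleep_apnea", "traffic_exposure",
    "smoking", "secondhand_smoke", "age", "sex", "bmi_group", "family_history",
]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, loadable from a YAML file."""

    seed: int = 0
    generator: dict = field(default_factory=dict)     # GeneratorConfig overrides
    k_min: int = 1
    k_max: int = 4
    restarts: int = 20
    tolerance: float = 1e-8
    constrained_rho: bool = False
    pattern_mapping: list | None = None               # list of [base, follow, pattern]
    pattern_fallback: str | None = "unclassified"
    reference_pattern: str = REFERENCE_PATTERN
    categorical_vars: list = field(default_factory=lambda: list(DEFAULT_CATEGORICAL_VARS))
    continuous_vars: list = field(default_factory=lambda: list(DEFAULT_CONTINUOUS_VARS))
    regression_terms: list = field(default_factory=lambda: list(DEFAULT_REGRESSION_TERMS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Independent 31-bit seed per stage, derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def generator_config(self) -> GeneratorConfig:
        kwargs = dict(self.generator)
        kwargs.setdefault("seed", self.stage_seed("simulate"))
        return GeneratorConfig(**kwargs)

    def em_options(self) -> EMOptions:
        return EMOptions(
            tol=self.tolerance,
            n_restarts=self.restarts,
            seed=self.stage_seed("fit"),
            constrained_rho=self.constrained_rho,
        )

    def mapping(self) -> PatternMapping:
        if self.pattern_mapping is None:
            return PatternMapping(fallback=self.pattern_fallback)
        table = {(a, b): p for a, b, p in self.pattern_mapping}
        return PatternMapping(table=table, fallback=self.pattern_fallback)


def _provenance(cfg: PipelineConfig) -> str:
    return f"seed={cfg.seed} config_hash={cfg.config_hash()} phenolta={__version__}"


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index=False) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {_provenance(cfg)}\n")
        df.to_csv(fh, index=index)


def cmd_simulate(cfg: PipelineConfig, outdir) -> Path:
    """Generate a cohort CSV plus a provenance record; returns the CSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_cfg = cfg.generator_config()
    cohort = generate_cohort(gen_cfg)
    cohort_path = outdir / "cohort.csv"
    write_cohort(cohort, cohort_path, header_comment=_provenance(cfg))
    prov = {
        "stage": "simulate",
        "seed": cfg.seed,
        "stage_seed": gen_cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "n_subjects": cohort.n,
    }
    (outdir / "simulate_provenance.json").write_text(json.dumps(prov, indent=2))
    logger.info("simulated %d subjects -> %s", cohort.n, cohort_path)
    return cohort_path


def cmd_fit(cfg: PipelineConfig, cohort_path, outdir) -> Path:
    """Select the class number by BIC and persist the winning model."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    panel = cohort.manifest_panel()
    options = cfg.em_options()
    fit, table = select_model(panel, cfg.k_max, options)
    if cfg.k_min > 1:
        from .lta import em_fit

        table = table[table["K"] >= cfg.k_min].reset_index(drop=True)
        if fit.K < cfg.k_min:
            ok = table.dropna(subset=["bic"])
            best_K = int(ok.sort_values(["bic", "K"]).iloc[0]["K"])
            fit = em_fit(panel, best_K, options)
    _write_csv(table, outdir / "bic_table.csv", cfg)
    model = {
        "provenance": _provenance(cfg),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "K": fit.K,
        "log_likelihood": fit.log_likelihood,
        "bic": fit.bic,
        "n_parameters": fit.n_parameters,
        "converged": fit.converged,
        "iteration_count": fit.iteration_count,
        "n_restarts_used": fit.n_restarts_used,
        "params": params_to_dict(fit.params),
    }
    model_path = outdir / "model.json"
    model_path.write_text(json.dumps(model, indent=2))
    _write_item_prob_report(fit, outdir / "item_probabilities.txt", cfg)
    logger.info("selected K=%d (BIC %.2f) -> %s", fit.K, fit.bic, model_path)
    return model_path


def _write_item_prob_report(fit, path: Path, cfg: PipelineConfig) -> None:
    """Human-readable item-probability table (% of item=1 per class and wave)."""
    rho = fit.params.rho
    K, J, T = rho.shape
    classes = CLASS_LABELS if K == len(CLASS_LABELS) else [f"class{k}" for k in range(K)]
    items = ITEM_NAMES if J == len(ITEM_NAMES) else [f"item{j}" for j in range(J)]
    waves = WAVE_LABELS if T == len(WAVE_LABELS) else [f"wave{t}" for t in range(T)]
    cols = pd.MultiIndex.from_product([waves, classes])
    mat = np.concatenate([rho[:, :, t].T for t in range(T)], axis=1)
    df = pd.DataFrame(np.round(100 * mat, 1), index=items, columns=cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_provenance(cfg)}\n")
        fh.write("Item-response probabilities (% reporting item, by class and wave)\n\n")
        fh.write(df.to_string())
        fh.write("\n\ndelta (initial class probabilities):\n")
        fh.write(pd.Series(fit.params.delta, index=classes).round(4).to_string())
        fh.write("\n\ntau (transition probabilities, rows = baseline class):\n")
        fh.write(pd.DataFrame(fit.params.tau, index=classes, columns=classes).round(4).to_string())
        fh.write("\n")


def cmd_patterns(cfg: PipelineConfig, cohort_path, model_path, outdir) -> Path:
    """Modal assignment, transition table, pattern prevalence."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    panel = cohort.manifest_panel()
    model = json.loads(Path(model_path).read_text())
    params = params_from_dict(model["params"])
    member = posterior_membership(panel, params)
    trans = transition_table(member)
    assignment = assign_patterns(member, cfg.mapping())

    K = member.K
    classes = CLASS_LABELS if K == len(CLASS_LABELS) else [f"class{k}" for k in range(K)]
    assignments = pd.DataFrame(
        {
            "id": cohort.data["id"].to_numpy(),
            "modal_baseline": [classes[k] for k in member.modal[:, 0]],
            "modal_followup": [classes[k] for k in member.modal[:, 1]],
            "pattern": assignment.labels,
        }
    )
    out_path = outdir / "assignments.csv"
    _write_csv(assignments, out_path, cfg)
    _write_csv(trans.to_frame(), outdir / "transition_counts.csv", cfg, index=True)
    _write_csv(
        trans.to_frame(percentages=True).round(1),
        outdir / "transition_row_pct.csv", cfg, index=True,
    )
    prev = assignment.to_frame().round({"percent": 1})
    prev.index.name = "pattern"
    _write_csv(prev, outdir / "pattern_prevalence.csv", cfg, index=True)
    logger.info("pattern prevalence:\n%s", prev.to_string())
    return out_path


def cmd_associate(cfg: PipelineConfig, cohort_path, assignments_path, outdir) -> dict:
    """Association reports: chi-square/residuals, ANOVA, multinomial ORs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    adf = pd.read_csv(assignments_path, comment="#", dtype=str)
    if "pattern" not in adf.columns:
        raise ValueError(
            "assignments file lacks a 'pattern' column; run the patterns stage first"
        )
    merged = cohort.data.merge(adf[["id", "pattern"]], on="id", validate="one_to_one")
    patterns_present = [p for p in PATTERN_LABELS if (merged["pattern"] == p).any()]
    extra = [p for p in merged["pattern"].unique() if p not in patterns_present]
    groups = patterns_present + sorted(extra)
    if len(groups) < 2:
        raise ValueError(
            "association analysis needs at least two longitudinal patterns; "
            f"this cohort has only {groups}"
        )

    cat_rows = []
    for var in cfg.categorical_vars:
        tab = pd.crosstab(merged[var], merged["pattern"])[
            [g for g in groups if g in set(merged["pattern"])]
        ]
        if tab.shape[0] < 2:
            logger.warning("variable '%s' is constant; skipped", var)
            continue
        res = chi2_with_residuals(tab.to_numpy())
        colsums = tab.sum(axis=0).to_numpy()
        for i, lev in enumerate(tab.index):
            row = {"variable": var, "level": lev, "chi2": round(res.chi2, 3),
                   "dof": res.dof, "p_value": res.p_value,
                   "significant": res.p_value < 0.05}
            for jdx, g in enumerate(tab.columns):
                pct = 100.0 * tab.to_numpy()[i, jdx] / colsums[jdx]
                flag = "*" if res.significant[i, jdx] else ""
                row[f"{g}_pct"] = f"{pct:.1f}{flag}"
            cat_rows.append(row)
    _write_csv(pd.DataFrame(cat_rows), outdir / "associations_categorical.csv", cfg)

    cont_rows = []
    for var in cfg.continuous_vars:
        grouped = [
            merged.loc[merged["pattern"] == g, var].astype(float).to_numpy()
            for g in groups
        ]
        grouped = [g for g in grouped if len(g)]
        res = anova_oneway(grouped)
        row = {"variable": var, "F": round(res.F, 3),
               "df_between": res.df_between, "df_within": res.df_within,
               "p_value": res.p_value, "significant": res.p_value < 0.05}
        for g in groups:
            vals = merged.loc[merged["pattern"] == g, var].astype(float)
            row[f"{g}_mean"] = round(vals.mean(), 1)
            row[f"{g}_sd"] = round(vals.std(ddof=1), 1)
        cont_rows.append(row)
    _write_csv(pd.DataFrame(cont_rows), outdir / "associations_continuous.csv", cfg)

    ref = cfg.reference_pattern
    reg_cohort = CohortTable(merged[merged["pattern"].isin(groups)].reset_index(drop=True))
    full, reduced, dropped = backward_eliminate(
        reg_cohort, reg_cohort.data["pattern"].to_numpy(), ref, cfg.regression_terms
    )
    _write_csv(full.summary_frame(), outdir / "regression_full.csv", cfg)
    _write_csv(reduced.summary_frame(), outdir / "regression_reduced.csv", cfg)
    if dropped:
        logger.info("terms dropped by backward pass: %s", dropped)
    return {
        "categorical": outdir / "associations_categorical.csv",
        "continuous": outdir / "associations_continuous.csv",
        "regression_full": outdir / "regression_full.csv",
        "regression_reduced": outdir / "regression_reduced.csv",
    }


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """simulate -> fit -> patterns -> associate, all under one output directory."""
    outdir = Path(outdir)
    cohort_path = cmd_simulate(cfg, outdir)
    model_path = cmd_fit(cfg, cohort_path, outdir)
    assignments_path = cmd_patterns(cfg, cohort_path, model_path, outdir)
    reports = cmd_associate(cfg, cohort_path, assignments_path, outdir)
    return {"cohort": cohort_path, "model": model_path,
            "assignments": assignments_path, **reports}
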