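"""Synthetic case-control cohorts with the structure the pipeline assumes.

Genotypes are drawn independently per SNP under Hardy–Weinberg
equilibrium at the panel effect-allele frequencies (the 11 panel SNPs
sit on 9 chromosomes, so linkage is ignored).  Covariates approximate a
European multi-center MPN study: four recruiting countries weighted by
the control margins, ~50% males, ages from a truncated normal.  Disease
is generated *prospectively* on a large subject pool through a logistic
model — a null model, injectable per-quintile log-odds acting on the
scaled-teloscore quintile, or injectable per-SNP per-effect-allele
log-odds — and cases/controls are then sampled to fixed margins.
Because logistic odds ratios are invariant to outcome-dependent
sampling, injected odds ratios are recoverable by the analysis stage.
Missingness is applied after sampling so the disease model always acts
on true genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

from .cohort import MISSING, Cohort
from .panel import PanelTable, builtin_panel
from .score import assign_quintile, control_quintile_cutpoints

__all__ = [
    "DiseaseModel",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "apply_missingness",
    "simulate_case_control",
]

# Control country margins of the study population the generator emulates.
_COUNTRY_CONTROLS = {"Hungary": 75, "Italy": 182, "Poland": 132, "Spain": 520}
# MPN subtype margins among cases (CML/ET/PMF/PV).
_SUBTYPE_CASES = {"CML": 149, "ET": 173, "PMF": 36, "PV": 122}


class DiseaseModel(BaseModel):
    """Logistic disease model for the simulated pool.

    ``kind`` selects the active effect: ``"null"`` (baseline only),
    ``"quintile_effects"`` (log-odds for scaled-score quintiles 2-5 vs
    quintile 1) or ``"per_snp"`` (per-effect-allele log-odds by rsid).
    ``baseline_log_odds`` sets pool prevalence, i.e. sampling
    efficiency; it does not affect odds ratios.
    """

    kind: Literal["null", "quintile_effects", "per_snp"] = "null"
    quintile_log_or: tuple[float, float, float, float] | None = None
    per_snp_log_or: dict[str, float] | None = None
    baseline_log_odds: float = -2.0

    @model_validator(mode="after")
    def _one_kind_active(self):
        if self.kind == "quintile_effects" and self.quintile_log_or is None:
            raise ValueError("quintile_effects model requires quintile_log_or")
        if self.kind == "per_snp" and not self.per_snp_log_or:
            raise ValueError("per_snp model requires per_snp_log_or")
        if self.kind == "null" and (self.quintile_log_or or self.per_snp_log_or):
            raise ValueError("null model must not carry effect parameters")
        for v in (self.quintile_log_or or ()):
            if not np.isfinite(v):
                raise ValueError("quintile log-ORs must be finite")
        for v in (self.per_snp_log_or or {}).values():
            if not np.isfinite(v):
                raise ValueError("per-SNP log-ORs must be finite")
        return self


class SimulationConfig(BaseModel):
    """Cohort-generator settings; defaults emulate the study margins."""

    n_cases: int = Field(480, gt=0)
    n_controls: int = Field(909, gt=0)
    country_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_COUNTRY_CONTROLS)
    )
    subtype_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_SUBTYPE_CASES)
    )
    male_fraction: float = Field(0.50, ge=0.0, le=1.0)
    age_mean: float = 53.0
    age_sd: float = Field(11.0, gt=0)
    age_range: tuple[float, float] = (18.0, 95.0)
    missing_rate: float = Field(0.03, ge=0.0, le=1.0)
    jak2_positive_fraction: float = Field(0.5, ge=0.0, le=1.0)
    disease_model: DiseaseModel = Field(default_factory=DiseaseModel)
    pool_factor: int = Field(20, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _weights_positive(self):
        for name, w in (("country_weights", self.country_weights),
                        ("subtype_weights", self.subtype_weights)):
            if not w or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError(f"{name} must be nonnegative with positive sum")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth that produced it."""

    cohort: Cohort
    truth: dict


def simulate_genotypes(n: int, panel: PanelTable, seed) -> np.ndarray:
    """n x panel matrix of HWE effect-allele counts (Binomial(2, EAF))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n, len(panel)), dtype=np.int8)
    for j, entry in enumerate(panel):
        out[:, j] = rng.binomial(2, entry.eaf, size=n)
    return out


def apply_missingness(matrix: np.ndarray, missing_rate: float, seed) -> np.ndarray:
    """Set each call missing independently with probability ``missing_rate``."""
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    out[rng.random(matrix.shape) < missing_rate] = MISSING
    return out


def _truncnorm_ages(n, cfg: SimulationConfig, rng) -> np.ndarray:
    lo, hi = cfg.age_range
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    return truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng)


def _categorical(weights: dict[str, float], n, rng) -> np.ndarray:
    labels = list(weights)
    p = np.array([weights[k] for k in labels], dtype=float)
    return rng.choice(labels, size=n, p=p / p.sum())


def _pool_linear_predictor(
    genotypes: np.ndarray, panel: PanelTable, model: DiseaseModel, rng
) -> tuple[np.ndarray, dict]:
    """Per-subject disease log-odds on the pool, plus truth metadata."""
    base = model.baseline_log_odds
    if model.kind == "null":
        return np.full(genotypes.shape[0], base), {}
    if model.kind == "per_snp":
        lp = np.full(genotypes.shape[0], base, dtype=float)
        for rsid, lor in model.per_snp_log_or.items():
            if rsid not in panel:
                raise ValueError(f"per_snp_log_or names {rsid!r}, not in panel")
            j = panel.rsids.index(rsid)
            lp += lor * genotypes[:, j]
        return lp, {}
    # quintile_effects: bins from the pool's prospective controls.  The
    # prospective control set is unknowable a priori, so a provisional
    # draw with pool-wide cutpoints defines a control population, whose
    # cutpoints then drive the final model (one refinement pass).
    weights = np.asarray(panel.bp_weights)
    scaled = genotypes.astype(np.int64) @ weights / len(panel)
    q_all = control_quintile_cutpoints(scaled)
    effects = np.concatenate([[0.0], np.asarray(model.quintile_log_or)])
    lp0 = base + effects[assign_quintile(scaled, q_all) - 1]
    provisional_case = rng.random(len(lp0)) < 1.0 / (1.0 + np.exp(-lp0))
    ctrl_scores = scaled[~provisional_case]
    cut = control_quintile_cutpoints(ctrl_scores) if ctrl_scores.size >= 5 else q_all
    lp = base + effects[assign_quintile(scaled, cut) - 1]
    return lp, {"truth_cutpoints": list(cut.thresholds), "true_scaled_scores": scaled}


def simulate_case_control(
    config: SimulationConfig, panel: PanelTable | None = None
) -> SimulatedCohort:
    """Generate a cohort of exactly n_cases + n_controls subjects.

    A pool of ``pool_factor * (n_cases + n_controls)`` subjects receives
    true genotypes and covariates; disease is drawn from the configured
    logistic model; the first n_cases cases and n_controls controls are
    kept and missingness is applied to the kept genotypes only.
    Deterministic: identical config (incl. seed) gives byte-identical
    output.
    """
    panel = panel or builtin_panel()
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_cov, s_disease, s_pheno, s_miss = ss.spawn(5)

    pool_n = config.pool_factor * (config.n_cases + config.n_controls)
    genotypes = simulate_genotypes(pool_n, panel, s_geno)

    rng_cov = np.random.default_rng(s_cov)
    ages = _truncnorm_ages(pool_n, config, rng_cov)
    sexes = np.where(rng_cov.random(pool_n) < config.male_fraction, "male", "female")
    countries = _categorical(config.country_weights, pool_n, rng_cov)

    rng_dis = np.random.default_rng(s_disease)
    lp, truth_extra = _pool_linear_predictor(genotypes, panel, config.disease_model, rng_dis)
    is_case = rng_dis.random(pool_n) < 1.0 / (1.0 + np.exp(-lp))

    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise RuntimeError(
            f"pool of {pool_n} yielded {len(case_idx)} cases / {len(ctrl_idx)} controls, "
            f"need {config.n_cases}/{config.n_controls}; increase pool_factor or "
            "adjust baseline_log_odds"
        )
    take = np.concatenate([case_idx[: config.n_cases], ctrl_idx[: config.n_controls]])

    rng_ph = np.random.default_rng(s_pheno)
    n_total = len(take)
    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    subtype = np.where(
        status == "case", _categorical(config.subtype_weights, n_total, rng_ph), "none"
    )
    jak2 = np.where(
        status == "case",
        np.where(
            rng_ph.random(n_total) < config.jak2_positive_fraction, "positive", "negative"
        ),
        "unknown",
    )

    ids = pd.Index([f"S{i + 1:05d}" for i in range(n_total)], name="subject_id")
    pheno = pd.DataFrame(
        {
            "status": status,
            "age": np.round(ages[take], 1),
            "sex": sexes[take],
            "country": countries[take],
            "subtype": subtype,
            "jak2": jak2,
        },
        index=ids,
    )
    observed = apply_missingness(genotypes[take], config.missing_rate, s_miss)
    geno = pd.DataFrame(observed, index=ids, columns=panel.rsids)
    cohort = Cohort(pheno, geno, panel)

    truth: dict = {
        "disease_model": config.disease_model.model_dump(),
        "seed": config.seed,
        "pool_size": pool_n,
    }
    if "true_scaled_scores" in truth_extra:
        truth["truth_cutpoints"] = truth_extra["truth_cutpoints"]
        truth["true_scaled_scores"] = pd.Series(
            truth_extra["true_scaled_scores"][take], index=ids
        )
    truth["true_genotypes"] = pd.DataFrame(genotypes[take], index=ids, columns=panel.rsids)
    return SimulatedCohort(cohort=cohort, truth=truth)
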