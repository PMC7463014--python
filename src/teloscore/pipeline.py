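"""End-to-end analysis runs: QC -> scores -> quintile and per-SNP models.

Mirrors the study's analysis order: the call-rate filter first, then the
Hardy–Weinberg report on the retained controls, scaled teloscores (raw
scores for fully called subjects), control-derived quintile cutpoints,
the quintile model (categorical + per-quintile trend), per-SNP models
with Bonferroni flags, and optional stratified and leave-one-out runs.

Also hosts the parameter-recovery experiments used to validate the
whole chain against known injected effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from .association import AssociationResult, apply_bonferroni, bonferroni_threshold
from .cohort import Cohort, filter_by_call_rate, hwe_control_report
from .panel import PanelTable, SnpDefinition, builtin_panel
from .score import QuintileCutpoints, cohort_scores, control_quintile_cutpoints
from .simulate import DiseaseModel, SimulationConfig, simulate_case_control

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisResult",
    "run_analysis",
    "write_results",
    "render_report",
    "recover_quintile_or",
    "recover_allelic_or",
    "TABLE3_SCALED_QUINTILE_ORS",
    "OBFC1_ALLELIC_OR",
]

#: Published highest-vs-lowest quintile effects (weighted-scaled score,
#: bins 2-5 vs 1) used as the default injection in recovery experiments.
TABLE3_SCALED_QUINTILE_ORS = (1.25, 1.65, 1.54, 1.82)
#: Published OBFC1 per-allele odds ratio used in per-SNP recovery.
OBFC1_ALLELIC_OR = 1.43


class QCError(RuntimeError):
    """Raised when quality control leaves too few subjects to analyze."""


@dataclass
class AnalysisResult:
    """Everything one analysis run produced."""

    cohort: Cohort
    exclusions: pd.DataFrame
    hwe: pd.DataFrame
    scores: pd.DataFrame
    cutpoints: QuintileCutpoints
    quintile_results: list[AssociationResult]
    snp_results: list[AssociationResult]
    stratified_results: list[AssociationResult] = field(default_factory=list)
    bonferroni: float = float("nan")
    settings: dict = field(default_factory=dict)

    @property
    def any_flagged(self) -> bool:
        return any(
            r.flagged and not r.omitted
            for r in self.quintile_results + self.snp_results + self.stratified_results
        )


def run_analysis(
    cohort: Cohort,
    min_called: int = 8,
    score_variant: str = "scaled",
    models: tuple[str, ...] = ("allelic", "codominant"),
    stratify: str | None = None,
    exclude_snps: tuple[str, ...] = (),
    cutpoints_mode: str = "per-stratum",
    hwe_method: str = "exact",
    covariates=assoc.DEFAULT_COVARIATES,
    min_subjects: int = 50,
) -> AnalysisResult:
    """Run the full association analysis on a QC'd-on-entry cohort.

    ``score_variant`` selects the headline score: ``"scaled"`` analyses
    all retained subjects on the per-genotype-scaled score; ``"raw"``
    restricts to subjects with a 100% call rate and uses the raw bp sum.
    ``exclude_snps`` removes SNPs from the score (leave-one-out runs)
    while per-SNP models still cover the full panel.
    """
    retained, exclusions = filter_by_call_rate(cohort, min_called)
    if len(retained) < min_subjects:
        raise QCError(
            f"call-rate filter left {len(retained)} subjects (<{min_subjects}); aborting"
        )
    if retained.n_cases == 0 or retained.n_controls == 0:
        raise QCError("QC left a single outcome class; nothing to model")

    hwe = hwe_control_report(retained, method=hwe_method)
    scores = cohort_scores(retained, excluded_rsids=list(exclude_snps) or None)

    if score_variant == "raw":
        score_col = scores["raw_score"]
    elif score_variant == "scaled":
        score_col = scores["scaled_score"]
    else:
        raise ValueError("score_variant must be 'scaled' or 'raw'")

    cutpoints = control_quintile_cutpoints(score_col[~retained.is_case])
    quintile_results = assoc.quintile_association(
        retained, score_col, cutpoints, covariates
    )

    n_models = len(models)
    threshold = bonferroni_threshold(len(retained.panel), n_models)
    snp_results: list[AssociationResult] = []
    for entry in retained.panel:
        for model in models:
            try:
                snp_results.extend(
                    assoc.snp_association(retained, entry.rsid, model, covariates)
                )
            except ValueError as exc:
                snp_results.append(
                    AssociationResult(
                        term="(not fitted)", odds_ratio=np.nan, ci_low=np.nan,
                        ci_high=np.nan, p_value=np.nan, model=model,
                        rsid=entry.rsid, flagged=True, omitted=True, note=str(exc),
                    )
                )
    snp_results = apply_bonferroni(snp_results, threshold)

    stratified: list[AssociationResult] = []
    if stratify:
        stratified = assoc.stratified_association(
            retained, stratify, "quintile",
            cutpoints=cutpoints, scores=score_col, covariates=covariates,
            cutpoints_mode=cutpoints_mode,
        )
        stratified += assoc.stratified_association(
            retained, stratify, "per_snp",
            covariates=covariates, models=models,
        )

    return AnalysisResult(
        cohort=retained,
        exclusions=exclusions,
        hwe=hwe,
        scores=scores.assign(
            quintile=np.where(
                score_col.notna(),
                _safe_quintiles(score_col, cutpoints),
                0,
            )
        ),
        cutpoints=cutpoints,
        quintile_results=quintile_results,
        snp_results=snp_results,
        stratified_results=stratified,
        bonferroni=threshold,
        settings={
            "min_called": min_called,
            "score_variant": score_variant,
            "models": list(models),
            "stratify": stratify,
            "exclude_snps": list(exclude_snps),
            "cutpoints_mode": cutpoints_mode,
            "hwe_method": hwe_method,
            "percentile_definition": "linear interpolation",
        },
    )


def _safe_quintiles(score_col: pd.Series, cutpoints: QuintileCutpoints) -> np.ndarray:
    from .score import assign_quintile

    return assign_quintile(score_col.to_numpy(dtype=float), cutpoints)


def write_results(result: AnalysisResult, outdir) -> dict[str, Path]:
    """Write machine-readable TSV/JSON outputs; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["scores"] = outdir / "scores.tsv"
    scores = result.scores.copy()
    scores.to_csv(paths["scores"], sep="\t", index_label="subject_id", na_rep="")

    paths["hwe"] = outdir / "hwe_controls.tsv"
    result.hwe.to_csv(paths["hwe"], sep="\t")

    paths["exclusions"] = outdir / "excluded_subjects.tsv"
    result.exclusions.to_csv(paths["exclusions"], sep="\t", index_label="subject_id")

    paths["quintile"] = outdir / "quintile_associations.tsv"
    assoc.results_to_frame(result.quintile_results + result.stratified_results).to_csv(
        paths["quintile"], sep="\t", index=False
    )

    paths["snp"] = outdir / "snp_associations.tsv"
    assoc.results_to_frame(result.snp_results).to_csv(paths["snp"], sep="\t", index=False)

    paths["run"] = outdir / "run_settings.json"
    with open(paths["run"], "w") as fh:
        json.dump(
            {
                "settings": result.settings,
                "bonferroni_threshold": result.bonferroni,
                "cutpoints": list(result.cutpoints.thresholds),
                "n_cases": result.cohort.n_cases,
                "n_controls": result.cohort.n_controls,
                "n_excluded": int(len(result.exclusions)),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths


def _fmt_or(r: AssociationResult) -> str:
    if r.omitted or not np.isfinite(r.odds_ratio):
        return "-       -            -"
    if r.note == "reference":
        return "1       -            Ref."
    return f"{r.odds_ratio:<7.2f} {r.ci_low:.2f}-{r.ci_high:<7.2f} {r.p_value:.2e}"


def render_report(results_dir) -> str:
    """Human-readable summary assembled from a results directory."""
    results_dir = Path(results_dir)
    run = results_dir / "run_settings.json"
    if not run.exists():
        raise FileNotFoundError(f"missing results file: {run}")
    with open(run) as fh:
        meta = json.load(fh)
    quintile = pd.read_csv(results_dir / "quintile_associations.tsv", sep="\t")
    snp = pd.read_csv(results_dir / "snp_associations.tsv", sep="\t")
    hwe = pd.read_csv(results_dir / "hwe_controls.tsv", sep="\t")
    excluded = pd.read_csv(results_dir / "excluded_subjects.tsv", sep="\t")

    lines = ["Teloscore analysis report", "=" * 60, ""]
    lines.append("Quality control")
    lines.append(
        f"  retained: {meta['n_cases']} cases / {meta['n_controls']} controls"
        f" (excluded {meta['n_excluded']} below the call-rate threshold)"
    )
    if len(excluded):
        by = excluded["status"].value_counts()
        lines.append(
            f"  excluded by status: {int(by.get('case', 0))} cases,"
            f" {int(by.get('control', 0))} controls"
        )
    n_hwe_fail = int((hwe["hwe_p"] < 0.05).sum())
    lines.append(
        f"  Hardy-Weinberg in controls: {n_hwe_fail} of {len(hwe)} SNPs with p < 0.05"
    )
    lines.append("")
    lines.append(
        "Quintile analysis (cutpoints from controls: "
        + ", ".join(f"{t:.2f}" for t in meta["cutpoints"])
        + " bp/genotype)"
    )
    lines.append("  stratum  model       term          OR      95% CI       p")
    for _, r in quintile.iterrows():
        rr = AssociationResult(
            term=r["term"], odds_ratio=r["odds_ratio"], ci_low=r["ci_low"],
            ci_high=r["ci_high"], p_value=r["p_value"],
            omitted=bool(r["omitted"]), note=str(r["note"]) if pd.notna(r["note"]) else "",
        )
        lines.append(
            f"  {r['stratum']:<8} {r['model']:<11} {r['term']:<13} {_fmt_or(rr)}"
        )
    lines.append("")
    lines.append(
        f"Per-SNP analysis (Bonferroni threshold p < {meta['bonferroni_threshold']:.4f})"
    )
    lines.append("  rsid        model       term                     OR      95% CI       p       sig")
    for _, r in snp.iterrows():
        rr = AssociationResult(
            term=r["term"], odds_ratio=r["odds_ratio"], ci_low=r["ci_low"],
            ci_high=r["ci_high"], p_value=r["p_value"],
            omitted=bool(r["omitted"]), note=str(r["note"]) if pd.notna(r["note"]) else "",
        )
        sig = "*" if str(r["significant_bonferroni"]) == "True" else ""
        lines.append(
            f"  {str(r['rsid']):<11} {r['model']:<11} {r['term']:<24} {_fmt_or(rr)} {sig}"
        )
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Parameter-recovery experiments
# ---------------------------------------------------------------------------

def _replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    # keep derived seeds in the signed 32-bit range
    return np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF


def recover_quintile_or(
    n_reps: int = 200,
    seed: int = 1,
    quintile_ors: tuple[float, float, float, float] = TABLE3_SCALED_QUINTILE_ORS,
    n_cases: int = 480,
    n_controls: int = 909,
) -> dict:
    """Inject quintile effects, re-analyze, and summarise Q5-vs-Q1 recovery.

    Each replicate simulates a cohort at the default study margins with
    the given per-quintile odds ratios wired into the disease model,
    runs the QC + scoring + adjusted quintile model, and records the
    estimated log-OR for quintile 5 vs 1.  The summary reports the
    geometric-mean OR (exp of the mean log-OR) with its Monte-Carlo
    standard error.
    """
    target_log = float(np.log(quintile_ors[-1]))
    log_ors = []
    for rep_seed in _replicate_seeds(seed, n_reps):
        cfg = SimulationConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            seed=int(rep_seed),
            disease_model=DiseaseModel(
                kind="quintile_effects",
                quintile_log_or=tuple(np.log(quintile_ors)),
            ),
        )
        sim = simulate_case_control(cfg)
        retained, _ = filter_by_call_rate(sim.cohort, 8)
        scores = cohort_scores(retained)["scaled_score"]
        cut = control_quintile_cutpoints(scores[~retained.is_case])
        res = assoc.quintile_association(retained, scores, cut)
        q5 = next(r for r in res if r.term == "quintile 5")
        if not q5.flagged:
            log_ors.append(np.log(q5.odds_ratio))
    log_ors = np.asarray(log_ors)
    mean_log = float(log_ors.mean())
    se_log = float(log_ors.std(ddof=1) / np.sqrt(len(log_ors)))
    return {
        "n_reps": int(len(log_ors)),
        "target_or": float(quintile_ors[-1]),
        "mean_log_or": mean_log,
        "se_log_or": se_log,
        "recovered_or": float(np.exp(mean_log)),
        "z_vs_target": (mean_log - target_log) / se_log if se_log > 0 else float("nan"),
    }


def _single_snp_panel(eaf: float) -> PanelTable:
    """Synthetic one-SNP panel for single-variant simulations."""
    return PanelTable(
        [
            SnpDefinition(
                rsid="rs_sim", gene="SIM", chromosome="1", position=1000,
                effect_allele="C", other_allele="A", eaf=eaf,
                beta=0.1, beta_se=0.01, bp_per_allele=120.0,
                discovery_pvalue=1e-8, discovery_study="synthetic",
            )
        ]
    )


def recover_allelic_or(
    n_reps: int = 200,
    seed: int = 2,
    eaf: float = 0.13,
    allelic_or: float = OBFC1_ALLELIC_OR,
    n_cases: int = 480,
    n_controls: int = 909,
) -> dict:
    """Inject a per-allele effect at one SNP and recover it end to end.

    Simulates a single SNP at the given effect-allele frequency under
    HWE, injects ``log(allelic_or)`` per effect-allele copy into the
    disease model, and fits the adjusted allelic (log-additive) model
    per replicate.  Summary as in :func:`recover_quintile_or`.
    """
    panel = _single_snp_panel(eaf)
    target_log = float(np.log(allelic_or))
    log_ors = []
    for rep_seed in _replicate_seeds(seed, n_reps):
        cfg = SimulationConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            seed=int(rep_seed),
            disease_model=DiseaseModel(
                kind="per_snp", per_snp_log_or={"rs_sim": target_log}
            ),
        )
        sim = simulate_case_control(cfg, panel=panel)
        retained, _ = filter_by_call_rate(sim.cohort, min_called=1)
        res = assoc.snp_association(retained, "rs_sim", "allelic")
        if not res[0].flagged:
            log_ors.append(np.log(res[0].odds_ratio))
    log_ors = np.asarray(log_ors)
    mean_log = float(log_ors.mean())
    se_log = float(log_ors.std(ddof=1) / np.sqrt(len(log_ors)))
    return {
        "n_reps": int(len(log_ors)),
        "target_or": float(allelic_or),
        "mean_log_or": mean_log,
        "se_log_or": se_log,
        "recovered_or": float(np.exp(mean_log)),
        "z_vs_target": (mean_log - target_log) / se_log if se_log > 0 else float("nan"),
    }
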