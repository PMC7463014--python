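"""Case-control association models for the score and individual SNPs.

All effects come from unconditional logistic regression of case status,
adjusted for age (continuous), sex and country of origin (indicator
terms, largest control category as reference).  Odds ratios carry Wald
95% confidence intervals ``exp(coef +/- 1.96 * se)`` and two-sided Wald
p-values; likelihood-ratio p-values are available as an option.

Genetic models for a single SNP, with m the minor allele (determined in
controls; a 0.5 tie makes the panel's other allele minor):

=========== =====================================================
allelic     single term counting minor-allele copies (log-additive)
codominant  two contrasts, Mm vs MM and mm vs MM
dominant    mm + Mm vs MM (carrier of >=1 minor allele)
recessive   mm vs Mm + MM
=========== =====================================================

Multiple testing across the panel uses Bonferroni over
(number of SNPs) x (number of models) tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .cohort import Cohort, MISSING, minor_allele_is_effect
from .score import QuintileCutpoints, assign_quintile

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "fit_logistic",
    "covariate_design",
    "quintile_association",
    "snp_association",
    "bonferroni_threshold",
    "apply_bonferroni",
    "stratified_association",
    "results_to_frame",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: |log-odds| beyond which a fitted contrast is treated as quasi-separated.
SEPARATION_BOUND = 15.0

DEFAULT_COVARIATES = ("age", "sex", "country")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit summary keyed by term name."""

    coefficients: pd.Series
    standard_errors: pd.Series
    converged: bool
    n_used: int
    log_likelihood: float
    flagged: bool = False  # non-convergence or quasi-separation

    def wald_result(self, term: str, **kw) -> "AssociationResult":
        b = float(self.coefficients[term])
        se = float(self.standard_errors[term])
        with np.errstate(over="ignore"):  # separated fits: CI may be infinite
            return AssociationResult(
                term=term,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - Z_95 * se)),
                ci_high=float(np.exp(b + Z_95 * se)),
                p_value=float(2 * norm.sf(abs(b) / se)) if se > 0 else float("nan"),
                n_used=self.n_used,
                flagged=self.flagged,
                **kw,
            )


@dataclass
class AssociationResult:
    """One odds-ratio contrast from a fitted model."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str = ""
    rsid: str = ""
    stratum: str = "all"
    n_used: int = 0
    significant_bonferroni: bool | None = None
    flagged: bool = False
    omitted: bool = False
    note: str = ""


def fit_logistic(outcome, design: pd.DataFrame, add_intercept: bool = True) -> LogisticFit:
    """Fit a logistic regression by Newton-type maximum likelihood.

    ``outcome`` is 0/1 per subject; ``design`` holds the predictor and
    covariate columns.  Quasi-separation (any |coef| > 15) or failed
    convergence flags the fit; downstream results inherit the flag.

    Raises
    ------
    ValueError
        If the outcome contains a single class.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic model undefined")
    X = design.astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # convergence failures are detected below and flag the fit
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # singular Hessian / perfect separation
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=0)
            converged = False
    coefs = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    predictor_cols = [c for c in X.columns if c != "const"]
    flagged = (not converged) or bool(
        (coefs[predictor_cols].abs() > SEPARATION_BOUND).any()
    )
    if flagged:
        logger.warning("flagged logistic fit (converged=%s)", converged)
    return LogisticFit(
        coefficients=coefs,
        standard_errors=bse,
        converged=converged,
        n_used=int(len(y)),
        log_likelihood=float(res.llf),
        flagged=flagged,
    )


def lrt_pvalue(outcome, design: pd.DataFrame, terms: list[str]) -> float:
    """Likelihood-ratio p-value for dropping ``terms`` from the design."""
    full = fit_logistic(outcome, design)
    reduced_design = design.drop(columns=terms)
    if reduced_design.shape[1] == 0:
        reduced_design = pd.DataFrame(index=design.index)
    reduced = fit_logistic(outcome, reduced_design)
    stat = 2 * (full.log_likelihood - reduced.log_likelihood)
    return float(chi2.sf(max(stat, 0.0), df=len(terms)))


def covariate_design(
    cohort: Cohort, covariates=DEFAULT_COVARIATES
) -> tuple[pd.DataFrame, pd.Series]:
    """Adjustment design matrix and the complete-case mask.

    Age enters in years; sex and country become indicator columns with
    the largest control category as the reference level.  Subjects with
    a missing adjustment covariate are excluded (complete-case) with a
    logged count.
    """
    pheno = cohort.phenotypes
    cols = {}
    mask = pd.Series(True, index=pheno.index)
    for cov in covariates:
        if cov == "age":
            mask &= pheno["age"].notna()
            cols["age"] = pheno["age"]
        elif cov in ("sex", "country"):
            values = pheno[cov].astype(str)
            mask &= values.notna() & (values != "nan")
            ctrl = values[pheno["status"] == "control"]
            ref = ctrl.value_counts().idxmax() if len(ctrl) else values.value_counts().idxmax()
            for level in sorted(values.unique()):
                if level != ref:
                    cols[f"{cov}[{level}]"] = (values == level).astype(float)
        else:
            raise ValueError(f"unsupported covariate {cov!r}")
    dropped = int((~mask).sum())
    if dropped:
        logger.info("complete-case covariate exclusion: %d subjects dropped", dropped)
    return pd.DataFrame(cols, index=pheno.index), mask


def bonferroni_threshold(n_snps: int, n_models: int, alpha: float = 0.05) -> float:
    """Bonferroni significance threshold ``alpha / (n_snps * n_models)``."""
    if n_snps < 1 or n_models < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_snps * n_models)


def apply_bonferroni(results: list[AssociationResult], threshold: float) -> list[AssociationResult]:
    """Set the significance flag on each result against ``threshold``."""
    return [
        replace(r, significant_bonferroni=(not r.omitted) and r.p_value < threshold)
        for r in results
    ]


def quintile_association(
    cohort: Cohort,
    scores: pd.Series,
    cutpoints: QuintileCutpoints,
    covariates=DEFAULT_COVARIATES,
    stratum: str = "all",
) -> list[AssociationResult]:
    """Quintile contrasts (bins 2-5 vs bin 1) plus the per-quintile trend.

    ``scores`` are per-subject scaled teloscores; subjects are binned
    against the control-derived ``cutpoints``.  The categorical model
    fits indicator terms for bins 2-5 with bin 1 as reference; a second
    fit enters the bin index 1-5 as one numeric term ("continuous",
    odds ratio per one-quintile increment).
    """
    scores = scores.reindex(cohort.phenotypes.index)
    design_cov, mask = covariate_design(cohort, covariates)
    mask &= scores.notna()
    y = cohort.is_case[mask].astype(int)
    bins = pd.Series(
        assign_quintile(scores[mask].to_numpy(), cutpoints), index=scores[mask].index
    )

    results: list[AssociationResult] = [
        AssociationResult(
            term="quintile 1", odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan,
            p_value=np.nan, model="quintile", stratum=stratum,
            n_used=int(mask.sum()), note="reference",
        )
    ]
    present = sorted(bins.unique())
    terms = []
    X = design_cov[mask].copy()
    for q in (2, 3, 4, 5):
        name = f"quintile {q}"
        if q in present:
            X.insert(len(terms), name, (bins == q).astype(float))
            terms.append(name)
    fit = fit_logistic(y, X)
    for q in (2, 3, 4, 5):
        name = f"quintile {q}"
        if q in present:
            results.append(fit.wald_result(name, model="quintile", stratum=stratum))
        else:
            results.append(
                AssociationResult(
                    term=name, odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_value=np.nan, model="quintile", stratum=stratum, flagged=True,
                    omitted=True, note="empty quintile bin among modeled subjects",
                )
            )

    Xc = design_cov[mask].copy()
    Xc.insert(0, "per-quintile", bins.astype(float))
    cfit = fit_logistic(y, Xc)
    results.append(cfit.wald_result("per-quintile", model="continuous", stratum=stratum))
    return results


def score_trend_association(
    cohort: Cohort, scores: pd.Series, covariates=DEFAULT_COVARIATES, stratum: str = "all"
) -> AssociationResult:
    """Optional variant: the raw scaled score (per 100 bp) as the trend term."""
    scores = scores.reindex(cohort.phenotypes.index)
    design_cov, mask = covariate_design(cohort, covariates)
    mask &= scores.notna()
    X = design_cov[mask].copy()
    X.insert(0, "per-100bp", scores[mask] / 100.0)
    fit = fit_logistic(cohort.is_case[mask].astype(int), X)
    return fit.wald_result("per-100bp", model="continuous-score", stratum=stratum)


def _minor_counts(cohort: Cohort, rsid: str) -> pd.Series:
    """Minor-allele copy count per subject (NaN where uncalled)."""
    g = cohort.genotypes[rsid].astype(float).replace(MISSING, np.nan)
    try:
        minor_is_ea = minor_allele_is_effect(cohort, rsid, "controls")
    except ValueError:
        minor_is_ea = minor_allele_is_effect(cohort, rsid, "all")
    return g if minor_is_ea else 2.0 - g


def snp_association(
    cohort: Cohort,
    rsid: str,
    model: str = "allelic",
    covariates=DEFAULT_COVARIATES,
    count_allele: str = "minor",
    stratum: str = "all",
) -> list[AssociationResult]:
    """Single-SNP association under one genetic model.

    ``count_allele`` = "minor" (default, matching MAF-oriented report
    tables) or "effect" (long-telomere allele, score-consistent
    orientation).  Subjects with that genotype missing are excluded from
    the fit; a monomorphic SNP raises; a codominant contrast with an
    empty rare-homozygote cell is omitted with a marker rather than
    fitted.
    """
    if model not in ("allelic", "codominant", "dominant", "recessive"):
        raise ValueError(f"unknown genetic model {model!r}")
    if count_allele == "minor":
        m = _minor_counts(cohort, rsid)
    elif count_allele == "effect":
        m = cohort.genotypes[rsid].astype(float).replace(MISSING, np.nan)
    else:
        raise ValueError("count_allele must be 'minor' or 'effect'")

    design_cov, mask = covariate_design(cohort, covariates)
    mask &= m.notna()
    m = m[mask]
    if m.nunique() < 2:
        raise ValueError(f"{rsid} is monomorphic among modeled subjects")
    y = cohort.is_case[mask].astype(int)
    X = design_cov[mask].copy()
    common = dict(model=model, rsid=rsid, stratum=stratum)

    if model == "allelic":
        X.insert(0, "per-allele", m)
        return [fit_logistic(y, X).wald_result("per-allele", **common)]
    if model == "dominant":
        X.insert(0, "carrier", (m >= 1).astype(float))
        return [fit_logistic(y, X).wald_result("carrier", **common)]
    if model == "recessive":
        X.insert(0, "rare-homozygote", (m == 2).astype(float))
        return [fit_logistic(y, X).wald_result("rare-homozygote", **common)]

    # codominant: het and rare-hom vs common-hom
    results: list[AssociationResult] = []
    have_hom = bool((m == 2).any())
    X.insert(0, "het vs common hom", (m == 1).astype(float))
    if have_hom:
        X.insert(1, "rare hom vs common hom", (m == 2).astype(float))
    fit = fit_logistic(y, X)
    results.append(fit.wald_result("het vs common hom", **common))
    if have_hom:
        results.append(fit.wald_result("rare hom vs common hom", **common))
    else:
        results.append(
            AssociationResult(
                term="rare hom vs common hom", odds_ratio=np.nan, ci_low=np.nan,
                ci_high=np.nan, p_value=np.nan, omitted=True,
                note="empty rare-homozygote cell", **common,
            )
        )
    return results


def stratified_association(
    cohort: Cohort,
    stratum_variable: str,
    analysis: str,
    cutpoints: QuintileCutpoints | None = None,
    scores: pd.Series | None = None,
    covariates=DEFAULT_COVARIATES,
    models=("allelic", "codominant"),
    cutpoints_mode: str = "per-stratum",
) -> list[AssociationResult]:
    """Repeat an analysis restricting cases to each stratum level.

    ``stratum_variable`` is "jak2" or "subtype"; controls (which carry
    no stratum label) are shared across all case strata.  Quintile
    cutpoints are recomputed from the analysis stratum's controls by
    default (``cutpoints_mode="per-stratum"``) or frozen at supplied
    overall ``cutpoints`` (``"overall"``).  Strata with < 10 cases are
    computed but flagged low-power; a stratum with zero cases yields a
    flagged marker and no fit.
    """
    from .score import cohort_scores, control_quintile_cutpoints

    col = {"jak2": "jak2", "subtype": "subtype"}[stratum_variable]
    case_mask = cohort.is_case
    levels = sorted(
        v for v in cohort.phenotypes.loc[case_mask, col].unique()
        if v not in ("none", "unknown") and not pd.isna(v)
    )
    out: list[AssociationResult] = []
    for level in levels:
        label = f"{stratum_variable}={level}"
        keep = (~case_mask) | (cohort.phenotypes[col] == level)
        sub = cohort.select(keep)
        if sub.n_cases == 0:
            out.append(
                AssociationResult(
                    term="(no fit)", odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_value=np.nan, model=analysis, stratum=label, flagged=True,
                    omitted=True, note="stratum has zero cases",
                )
            )
            continue
        low_power = sub.n_cases < 10
        if analysis == "quintile":
            sub_scores = (
                scores.reindex(sub.phenotypes.index)
                if scores is not None
                else cohort_scores(sub)["scaled_score"]
            )
            if cutpoints_mode == "per-stratum" or cutpoints is None:
                cp = control_quintile_cutpoints(sub_scores[~sub.is_case])
            else:
                cp = cutpoints
            res = quintile_association(sub, sub_scores, cp, covariates, stratum=label)
        elif analysis == "per_snp":
            res = []
            for e in sub.panel:
                for model in models:
                    try:
                        res.extend(
                            snp_association(sub, e.rsid, model, covariates, stratum=label)
                        )
                    except ValueError as exc:
                        res.append(
                            AssociationResult(
                                term="(not fitted)", odds_ratio=np.nan, ci_low=np.nan,
                                ci_high=np.nan, p_value=np.nan, model=model, rsid=e.rsid,
                                stratum=label, flagged=True, omitted=True, note=str(exc),
                            )
                        )
        else:
            raise ValueError(f"unknown analysis {analysis!r}")
        if low_power:
            res = [replace(r, flagged=True, note=(r.note + "; low power (<10 cases)").lstrip("; ")) for r in res]
        out.extend(res)
    return out


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results into a full-precision table (one row per term)."""
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "model": r.model,
                "rsid": r.rsid,
                "term": r.term,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_used": r.n_used,
                "significant_bonferroni": r.significant_bonferroni,
                "flagged": r.flagged,
                "omitted": r.omitted,
                "note": r.note,
            }
            for r in results
        ]
    )
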