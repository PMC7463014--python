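"""Logistic association models: oracles, genetic-model codings, strata."""

import numpy as np
import pandas as pd
import pytest

from teloscore import (
    DiseaseModel,
    SimulationConfig,
    bonferroni_threshold,
    cohort_scores,
    control_quintile_cutpoints,
    fit_logistic,
    filter_by_call_rate,
    quintile_association,
    simulate_case_control,
    snp_association,
    stratified_association,
)
from teloscore.score import QuintileCutpoints
from conftest import make_cohort


def two_by_two_design(case_exposed, case_unexposed, ctrl_exposed, ctrl_unexposed):
    y = [1] * (case_exposed + case_unexposed) + [0] * (ctrl_exposed + ctrl_unexposed)
    x = (
        [1] * case_exposed + [0] * case_unexposed
        + [1] * ctrl_exposed + [0] * ctrl_unexposed
    )
    return np.array(y), pd.DataFrame({"exposed": x})


def test_logistic_or_equals_cross_product_ratio():
    """Saturated 2x2 fit reproduces ad/bc to 6 significant digits."""
    y, X = two_by_two_design(30, 70, 10, 90)
    fit = fit_logistic(y, X)
    expected = (30 * 90) / (70 * 10)
    assert np.exp(fit.coefficients["exposed"]) == pytest.approx(expected, rel=1e-6)
    r = fit.wald_result("exposed")
    assert r.ci_low <= r.odds_ratio <= r.ci_high


def test_null_predictor_gives_or_near_one():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=4000)
    X = pd.DataFrame({"x": rng.normal(size=4000)})
    fit = fit_logistic(y, X)
    assert np.exp(fit.coefficients["x"]) == pytest.approx(1.0, abs=0.1)


def test_single_class_outcome_rejected():
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(np.ones(20), pd.DataFrame({"x": np.arange(20.0)}))


def test_relabeling_outcome_inverts_odds_ratio():
    y, X = two_by_two_design(30, 70, 10, 90)
    a = fit_logistic(y, X).coefficients["exposed"]
    b = fit_logistic(1 - y, X).coefficients["exposed"]
    assert a == pytest.approx(-b, abs=1e-8)


def test_wald_consistency():
    """p < 0.05 exactly when 1 lies outside the 95% CI."""
    rng = np.random.default_rng(1)
    for effect in (0.0, 0.3, 0.8):
        x = rng.integers(0, 3, size=800)
        p = 1 / (1 + np.exp(-(-0.5 + effect * x)))
        y = rng.random(800) < p
        fit = fit_logistic(y.astype(int), pd.DataFrame({"x": x.astype(float)}))
        r = fit.wald_result("x")
        outside = r.ci_low > 1.0 or r.ci_high < 1.0
        assert (r.p_value < 0.05) == outside


def test_bonferroni_threshold():
    assert round(bonferroni_threshold(11, 2), 4) == 0.0023
    assert bonferroni_threshold(1, 1) == 0.05
    assert bonferroni_threshold(22, 1) == bonferroni_threshold(11, 2)
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 2)


def _genotype_cohort(panel, case_counts, ctrl_counts, rsid_idx=0):
    """Cohort whose first-SNP genotype counts (hom-common, het, hom-rare)
    are as given; all other SNPs heterozygous."""
    genotypes, phenotypes = {}, {}
    i = 0
    for status, (n0, n1, n2) in (("case", case_counts), ("control", ctrl_counts)):
        for geno, n in ((0, n0), (1, n1), (2, n2)):
            for _ in range(n):
                row = [1] * 11
                row[rsid_idx] = geno
                genotypes[f"S{i}"] = row
                phenotypes[f"S{i}"] = {"status": status}
                i += 1
    return make_cohort(panel, genotypes, phenotypes)


def test_allelic_model_matches_allele_table_cross_product(panel):
    # case alleles 60 minor / 140 major; control alleles 50 / 250
    cohort = _genotype_cohort(panel, (50, 40, 10), (105, 40, 5))
    res = snp_association(cohort, panel.rsids[0], "allelic", covariates=())
    expected = (60 * 250) / (140 * 50)  # ~2.143, asymptotic equivalence
    assert res[0].odds_ratio == pytest.approx(expected, rel=0.10)


def test_monomorphic_snp_rejected(panel):
    cohort = _genotype_cohort(panel, (100, 0, 0), (100, 0, 0))
    with pytest.raises(ValueError, match="monomorphic"):
        snp_association(cohort, panel.rsids[0], "allelic", covariates=())


def test_codominant_empty_rare_homozygote_is_omitted(panel):
    cohort = _genotype_cohort(panel, (60, 40, 0), (70, 30, 0))
    res = snp_association(cohort, panel.rsids[0], "codominant", covariates=())
    terms = {r.term: r for r in res}
    assert not terms["het vs common hom"].omitted
    hom = terms["rare hom vs common hom"]
    assert hom.omitted and np.isnan(hom.odds_ratio)


def test_dominant_and_recessive_codings(panel):
    cohort = _genotype_cohort(panel, (50, 30, 20), (70, 25, 5))
    dom = snp_association(cohort, panel.rsids[0], "dominant", covariates=())[0]
    # carrier 2x2: cases 50/50, controls 30/70
    assert dom.odds_ratio == pytest.approx((50 * 70) / (50 * 30), rel=1e-5)
    rec = snp_association(cohort, panel.rsids[0], "recessive", covariates=())[0]
    # rare-homozygote 2x2: cases 20/80, controls 5/95
    assert rec.odds_ratio == pytest.approx((20 * 95) / (80 * 5), rel=1e-5)


def test_minor_allele_orientation(panel):
    """For a SNP with effect-allele frequency > 0.5 the minor allele is
    the other allele, so allelic ORs under both orientations are inverse."""
    idx = panel.rsids.index("rs3027234")  # EAF 0.78
    cohort = _genotype_cohort(panel, (5, 40, 55), (10, 40, 50), rsid_idx=idx)
    minor = snp_association(cohort, "rs3027234", "allelic", covariates=())[0]
    effect = snp_association(
        cohort, "rs3027234", "allelic", covariates=(), count_allele="effect"
    )[0]
    assert minor.odds_ratio == pytest.approx(1 / effect.odds_ratio, rel=1e-6)


def test_quintile_reference_and_null(null_cohort):
    scores = cohort_scores(null_cohort)["scaled_score"]
    cut = control_quintile_cutpoints(scores[~null_cohort.is_case])
    res = quintile_association(null_cohort, scores, cut)
    by_term = {r.term: r for r in res}
    assert by_term["quintile 1"].odds_ratio == 1.0
    assert by_term["quintile 1"].note == "reference"
    for q in (2, 3, 4, 5):
        assert 0.6 < by_term[f"quintile {q}"].odds_ratio < 1.6
    assert len(res) == 6  # 5 quintile rows + continuous trend


def test_quintile_empty_bin_flagged(panel):
    genotypes = {f"S{i}": [i % 3] * 11 for i in range(40)}
    phenotypes = {f"S{i}": {"status": "case" if i % 2 else "control"} for i in range(40)}
    cohort = make_cohort(panel, genotypes, phenotypes)
    scores = cohort_scores(cohort)["scaled_score"]
    # external cutpoints placed so no subject lands in bin 5
    cut = QuintileCutpoints((50.0, 80.0, 120.0, 1e6))
    res = quintile_association(cohort, scores, cut, covariates=())
    q5 = next(r for r in res if r.term == "quintile 5")
    assert q5.omitted and q5.flagged


def test_stratified_single_stratum_matches_unstratified(null_cohort):
    pheno = null_cohort.phenotypes.copy()
    pheno.loc[pheno["status"] == "case", "jak2"] = "positive"
    cohort = type(null_cohort)(pheno, null_cohort.genotypes, null_cohort.panel)
    scores = cohort_scores(cohort)["scaled_score"]
    cut = control_quintile_cutpoints(scores[~cohort.is_case])
    strat = stratified_association(cohort, "jak2", "quintile", cutpoints=cut, scores=scores)
    plain = quintile_association(cohort, scores, cut)
    assert len(strat) == len(plain)
    for s, p in zip(strat, plain):
        assert s.stratum == "jak2=positive"
        assert s.odds_ratio == pytest.approx(p.odds_ratio, nan_ok=True)


def test_stratified_effect_confined_to_one_stratum(panel):
    """When only JAK2+ cases carry a per-SNP effect, the JAK2+ stratum
    recovers it and the JAK2- stratum stays near the null."""
    lor = float(np.log(2.2))
    eff = simulate_case_control(
        SimulationConfig(
            seed=23, n_cases=240, n_controls=909,
            disease_model=DiseaseModel(kind="per_snp", per_snp_log_or={"rs9420907": lor}),
        )
    ).cohort
    nul = simulate_case_control(
        SimulationConfig(seed=24, n_cases=240, n_controls=909)
    ).cohort

    pos_pheno = eff.phenotypes[eff.is_case].copy()
    pos_pheno["jak2"] = "positive"
    pos_pheno.index = "P" + pos_pheno.index
    pos_geno = eff.genotypes[eff.is_case.to_numpy()].copy()
    pos_geno.index = pos_pheno.index
    neg_pheno = nul.phenotypes.copy()
    neg_pheno.loc[neg_pheno["status"] == "case", "jak2"] = "negative"

    cohort = type(eff)(
        pd.concat([pos_pheno, neg_pheno]), pd.concat([pos_geno, nul.genotypes]), panel
    )

    res = stratified_association(cohort, "jak2", "per_snp", models=("allelic",))
    by = {(r.stratum, r.rsid): r for r in res if r.model == "allelic"}
    assert len([r for r in res if r.stratum == "jak2=positive"]) == 11
    # OBFC1's minor allele is its effect allele, so orientation is stable
    assert by[("jak2=positive", "rs9420907")].odds_ratio > 1.5
    assert 0.7 < by[("jak2=negative", "rs9420907")].odds_ratio < 1.4


def test_stratified_zero_and_low_count_cases(null_cohort):
    pheno = null_cohort.phenotypes.copy()
    pheno.loc[pheno["status"] == "case", "jak2"] = "positive"
    case_ids = pheno.index[pheno["status"] == "case"]
    pheno.loc[case_ids[:5], "jak2"] = "negative"
    cohort = type(null_cohort)(pheno, null_cohort.genotypes, null_cohort.panel)
    scores = cohort_scores(cohort)["scaled_score"]
    cut = control_quintile_cutpoints(scores[~cohort.is_case])
    res = stratified_association(cohort, "jak2", "quintile", cutpoints=cut, scores=scores)
    neg = [r for r in res if r.stratum == "jak2=negative"]
    assert neg and all(r.flagged for r in neg)  # <10 cases: computed but flagged
    assert all("low power" in r.note for r in neg)
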