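"""Cohort readers, call-rate QC, MAF and duplicate concordance."""

import numpy as np
import pandas as pd
import pytest

from teloscore import (
    MISSING,
    SimulationConfig,
    call_rate,
    duplicate_concordance,
    filter_by_call_rate,
    minor_allele_frequency,
    read_genotype_table,
    read_vcf_panel,
    simulate_case_control,
    write_genotype_table,
    write_phenotype_table,
)
from conftest import make_cohort


def _write_tables(tmp_path, panel, geno_rows, pheno_rows, pheno_header=None):
    gpath = tmp_path / "geno.tsv"
    ppath = tmp_path / "pheno.tsv"
    gpath.write_text(
        "subject_id\t" + "\t".join(panel.rsids) + "\n"
        + "\n".join("\t".join(str(v) for v in row) for row in geno_rows) + "\n"
    )
    header = pheno_header or "subject_id\tstatus\tage\tsex\tcountry\tsubtype\tjak2"
    ppath.write_text(header + "\n" + "\n".join(pheno_rows) + "\n")
    return gpath, ppath


PHENO3 = [
    "A\tcase\t60\tmale\tItaly\tET\tpositive",
    "B\tcontrol\t55\tfemale\tSpain\tnone\tunknown",
    "C\tcontrol\t50\tmale\tPoland\tnone\tunknown",
]


def test_read_complete_fixture(tmp_path, panel):
    rows = [["A"] + [1] * 11, ["B"] + [0] * 11, ["C"] + [2] * 11]
    cohort = read_genotype_table(*_write_tables(tmp_path, panel, rows, PHENO3), panel)
    assert len(cohort) == 3
    assert cohort.n_cases == 1 and cohort.n_controls == 2
    assert (cohort.genotypes.loc["C"] == 2).all()
    subj = cohort.subject("A")
    assert subj.status == "case" and subj.jak2_v617f == "positive"


def test_missing_and_unknown_codes_become_missing(tmp_path, panel):
    rows = [["A", "NA", ".", "", "weird"] + [1] * 7, ["B"] + [0] * 11, ["C"] + [1] * 11]
    cohort = read_genotype_table(*_write_tables(tmp_path, panel, rows, PHENO3), panel)
    assert (cohort.genotypes.loc["A"].iloc[:4] == MISSING).all()
    assert (cohort.genotypes.loc["A"].iloc[4:] == 1).all()


def test_duplicate_subject_id_rejected(tmp_path, panel):
    rows = [["A"] + [1] * 11, ["A"] + [0] * 11, ["C"] + [1] * 11]
    with pytest.raises(ValueError, match="duplicated subject_id"):
        read_genotype_table(*_write_tables(tmp_path, panel, rows, PHENO3), panel)


def test_missing_phenotype_column_rejected(tmp_path, panel):
    rows = [["A"] + [1] * 11]
    paths = _write_tables(
        tmp_path, panel, rows, ["A\tcase\t60\tmale\tItaly\tET"],
        pheno_header="subject_id\tstatus\tage\tsex\tcountry\tsubtype",
    )
    with pytest.raises(ValueError, match="jak2"):
        read_genotype_table(*paths, panel)


def test_table_round_trip_preserves_calls(tmp_path, panel):
    cohort = simulate_case_control(SimulationConfig(seed=3, n_cases=20, n_controls=40)).cohort
    write_genotype_table(cohort, tmp_path / "g.tsv")
    write_phenotype_table(cohort, tmp_path / "p.tsv")
    back = read_genotype_table(tmp_path / "g.tsv", tmp_path / "p.tsv", panel)
    pd.testing.assert_frame_equal(back.genotypes, cohort.genotypes)


@pytest.mark.parametrize(
    "n_called,expected", [(11, 1.0), (8, 0.727), (0, 0.0)]
)
def test_call_rate(panel, n_called, expected):
    g = np.array([1] * n_called + [MISSING] * (11 - n_called), dtype=np.int8)
    frac, count = call_rate(g, panel)
    assert count == n_called
    assert round(frac, 3) == expected


def test_call_rate_filter_reproduces_study_exclusions(panel):
    """503 cases / 929 controls with 23+20 low-call subjects -> 480/909."""
    sim = simulate_case_control(
        SimulationConfig(seed=5, n_cases=503, n_controls=929, missing_rate=0.0)
    )
    cohort = sim.cohort
    # force exactly 23 cases and 20 controls below 8 called SNPs
    case_ids = cohort.phenotypes.index[cohort.is_case][:23]
    ctrl_ids = cohort.phenotypes.index[~cohort.is_case][:20]
    for ids in (case_ids, ctrl_ids):
        cohort.genotypes.loc[ids, cohort.genotypes.columns[:4]] = MISSING
    retained, excluded = filter_by_call_rate(cohort, min_called=8)
    assert retained.n_cases == 480 and retained.n_controls == 909
    assert len(retained) == 1389
    assert len(excluded) == 43 and len(retained) + len(excluded) == len(cohort)
    # idempotent
    again, none_excluded = filter_by_call_rate(retained, min_called=8)
    assert len(again) == len(retained) and len(none_excluded) == 0


def test_call_rate_filter_noop_cases(panel):
    cohort = make_cohort(panel, {"A": [1] * 11, "B": [0] * 11})
    retained, excluded = filter_by_call_rate(cohort, min_called=8)
    assert len(retained) == 2 and len(excluded) == 0
    retained, _ = filter_by_call_rate(
        make_cohort(panel, {"A": [MISSING] * 11}), min_called=0
    )
    assert len(retained) == 1
    with pytest.raises(ValueError):
        filter_by_call_rate(cohort, min_called=12)


def test_minor_allele_frequency(panel):
    rsid = panel.rsids[0]
    all_het = make_cohort(panel, {f"S{i}": [1] * 11 for i in range(10)})
    assert minor_allele_frequency(all_het, rsid) == 0.5

    counts = {}
    i = 0
    for geno, n in ((2, 9), (1, 42), (0, 49)):
        for _ in range(n):
            counts[f"S{i}"] = [geno] * 11
            i += 1
    cohort = make_cohort(panel, counts)
    assert minor_allele_frequency(cohort, rsid) == pytest.approx(0.30)

    with pytest.raises(ValueError, match="stratum"):
        minor_allele_frequency(cohort, rsid, "cases")  # no cases present


def test_duplicate_concordance(panel):
    base = [1] * 11
    discordant = [1] * 10 + [2]
    partial = [MISSING] + [1] * 10
    cohort = make_cohort(
        panel,
        {"A": base, "A2": base, "B": partial, "B2": discordant,
         "C": [MISSING] * 11, "C2": [MISSING] * 11},
    )
    assert duplicate_concordance(cohort, [("A", "A2")]) == 1.0
    # 10 comparable calls, 1 discordant
    assert duplicate_concordance(cohort, [("B", "B2")]) == pytest.approx(0.9)
    with pytest.raises(ValueError, match="comparable"):
        duplicate_concordance(cohort, [("C", "C2")])


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=5>
##contig=<ID=10>
##contig=<ID=19>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
"""

VCF_BODY = (
    # OBFC1 site: ALT is the effect allele (C), direct orientation
    "10\t103916707\trs9420907\tA\tC\t.\tPASS\t.\tGT\t0/1\t1/1\t./.\n"
    # TERT site: REF is the effect allele (C) -> counts recoded 2 - alt
    "5\t1286401\trs2736100\tC\tA\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1\n"
    # ZNF676 position with an inconsistent allele pair -> skipped
    "19\t22359440\trs412658\tG\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1\n"
)


def test_read_vcf_panel_orientation_and_missing(tmp_path, panel):
    vcf_path = tmp_path / "panel.vcf"
    vcf_path.write_text(VCF_HEADER + VCF_BODY)
    geno = read_vcf_panel(vcf_path, panel)
    assert list(geno.index) == ["A", "B", "C"]
    # direct orientation: GT alt-count is the effect-allele count
    assert geno.loc["A", "rs9420907"] == 1
    assert geno.loc["B", "rs9420907"] == 2
    assert geno.loc["C", "rs9420907"] == MISSING  # ./.
    # flipped orientation: hom-ALT means zero effect alleles
    assert geno.loc["A", "rs2736100"] == 0
    assert geno.loc["B", "rs2736100"] == 2
    assert geno.loc["C", "rs2736100"] == 1
    # inconsistent allele pair skipped, all other panel sites absent
    assert (geno["rs412658"] == MISSING).all()
    assert (geno["rs10936599"] == MISSING).all()


def test_vcf_to_table_round_trip(tmp_path, panel):
    vcf_path = tmp_path / "panel.vcf"
    vcf_path.write_text(VCF_HEADER + VCF_BODY)
    geno = read_vcf_panel(vcf_path, panel)
    pheno = {sid: {} for sid in geno.index}
    cohort = make_cohort(panel, {sid: geno.loc[sid].tolist() for sid in geno.index}, pheno)
    write_genotype_table(cohort, tmp_path / "g.tsv")
    write_phenotype_table(cohort, tmp_path / "p.tsv")
    back = read_genotype_table(tmp_path / "g.tsv", tmp_path / "p.tsv", panel)
    pd.testing.assert_frame_equal(back.genotypes, cohort.genotypes)
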