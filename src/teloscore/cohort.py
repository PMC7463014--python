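"""Cohort data model, TSV/VCF readers and the genotyping QC steps.

A :class:`Cohort` pairs a phenotype table (case/control status, age, sex,
country, disease subtype, JAK2 V617F status) with a subjects x panel-SNPs
matrix of effect-allele counts.  Genotypes are stored as ``int8`` with
``-1`` marking a missing call.

QC mirrors a TaqMan panel workflow: a per-subject call-rate filter
(subjects need at least ``min_called`` of the panel SNPs called),
Hardy–Weinberg testing in controls, minor-allele frequencies, and
concordance of deliberately duplicated samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelTable
from .qc import hwe_chisq_test, hwe_exact_test

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "Subject",
    "Cohort",
    "read_genotype_table",
    "read_vcf_panel",
    "write_genotype_table",
    "write_phenotype_table",
    "call_rate",
    "filter_by_call_rate",
    "minor_allele_frequency",
    "duplicate_concordance",
    "genotype_counts",
    "hwe_control_report",
]

#: Sentinel for an uncalled genotype in the integer matrix.
MISSING: int = -1

PHENOTYPE_COLUMNS = ["subject_id", "status", "age", "sex", "country", "subtype", "jak2"]

#: Accepted spellings of a missing genotype call in the TSV dialect.
_MISSING_TOKENS = {"NA", "", ".", "nan", "NaN"}


@dataclass
class Subject:
    """One study subject: phenotype plus the panel genotype vector."""

    subject_id: str
    status: str  # "case" | "control"
    age: float | None
    sex: str  # "male" | "female"
    country: str
    subtype: str  # CML|ET|PMF|PV|none
    jak2_v617f: str  # positive|negative|unknown
    genotypes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))


@dataclass
class Cohort:
    """Phenotype table plus genotype matrix, aligned on subject_id.

    ``phenotypes`` is indexed by subject_id; ``genotypes`` shares that
    index and has one ``int8`` column per panel rsid (``-1`` = missing).
    """

    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    panel: PanelTable

    def __post_init__(self):
        if not self.phenotypes.index.is_unique:
            dupes = self.phenotypes.index[self.phenotypes.index.duplicated()]
            raise ValueError(f"duplicated subject_id: {sorted(set(dupes))}")
        if list(self.genotypes.columns) != self.panel.rsids:
            raise ValueError("genotype columns must match panel rsids in order")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("genotype and phenotype tables index different subjects")

    def __len__(self) -> int:
        return len(self.phenotypes)

    @property
    def n_cases(self) -> int:
        return int((self.phenotypes["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotypes["status"] == "control").sum())

    @property
    def is_case(self) -> pd.Series:
        return self.phenotypes["status"] == "case"

    def subject(self, subject_id: str) -> Subject:
        row = self.phenotypes.loc[subject_id]
        return Subject(
            subject_id=subject_id,
            status=row["status"],
            age=None if pd.isna(row["age"]) else float(row["age"]),
            sex=row["sex"],
            country=row["country"],
            subtype=row["subtype"],
            jak2_v617f=row["jak2"],
            genotypes=self.genotypes.loc[subject_id].to_numpy(dtype=np.int8),
        )

    def select(self, mask: pd.Series) -> "Cohort":
        """Row-subset by a boolean mask aligned to the subject index."""
        return Cohort(self.phenotypes.loc[mask].copy(), self.genotypes.loc[mask].copy(), self.panel)


def _parse_genotype_cell(value: str, rsid: str, subject_id: str) -> int:
    token = str(value).strip()
    if token in _MISSING_TOKENS:
        return MISSING
    if token in {"0", "1", "2"}:
        return int(token)
    # float spellings like "1.0" tolerated
    try:
        f = float(token)
        if f in (0.0, 1.0, 2.0):
            return int(f)
    except ValueError:
        pass
    logger.warning("unknown genotype code %r for %s/%s treated as missing", value, subject_id, rsid)
    return MISSING


def read_genotype_table(genotype_path, phenotype_path, panel: PanelTable) -> Cohort:
    """Read the TSV pair (genotypes, phenotypes) into a :class:`Cohort`.

    The genotype table has one row per subject: ``subject_id`` then one
    column per panel rsid holding effect-allele counts 0/1/2 or ``NA``.
    Unknown genotype codes become missing with a logged warning;
    duplicated subject ids or absent phenotype columns are errors.
    """
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str)
    if "subject_id" not in geno.columns:
        raise ValueError("genotype table lacks a subject_id column")
    missing_snps = [r for r in panel.rsids if r not in geno.columns]
    if missing_snps:
        raise ValueError(f"genotype table lacks panel columns: {missing_snps}")
    if geno["subject_id"].duplicated().any():
        dupes = geno.loc[geno["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject_id in genotype table: {dupes}")

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"subject_id": str})
    absent = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if absent:
        raise ValueError(f"phenotype table lacks required columns: {absent}")
    if pheno["subject_id"].duplicated().any():
        dupes = pheno.loc[pheno["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject_id in phenotype table: {dupes}")

    geno = geno.set_index("subject_id")
    pheno = pheno.set_index("subject_id")
    if set(geno.index) != set(pheno.index):
        raise ValueError("genotype and phenotype tables list different subjects")
    geno = geno.loc[pheno.index, panel.rsids]

    parsed = pd.DataFrame(
        {
            rsid: [
                _parse_genotype_cell(v, rsid, sid)
                for sid, v in zip(geno.index, geno[rsid])
            ]
            for rsid in panel.rsids
        },
        index=geno.index,
        dtype=np.int8,
    )
    pheno["age"] = pd.to_numeric(pheno["age"], errors="coerce")
    return Cohort(pheno[[c for c in PHENOTYPE_COLUMNS if c != "subject_id"]], parsed, panel)


def write_genotype_table(cohort: Cohort, path) -> None:
    """Write the genotype matrix as TSV with ``NA`` for missing calls."""
    out = cohort.genotypes.astype(object).where(cohort.genotypes != MISSING, "NA")
    out.to_csv(path, sep="\t", index_label="subject_id")


def write_phenotype_table(cohort: Cohort, path) -> None:
    cohort.phenotypes.to_csv(path, sep="\t", index_label="subject_id")


def read_vcf_panel(vcf_path, panel: PanelTable) -> pd.DataFrame:
    """Extract effect-allele counts for the panel sites from a VCF.

    Sites are matched by chromosome + position + allele pair.  When the
    VCF's ALT is the panel's effect allele the diploid GT alt-count is
    used directly; when the orientation is flipped (REF = effect allele)
    the count is recoded as ``2 - count``.  A matched position whose
    allele pair disagrees with the panel is skipped with a warning, and
    panel sites absent from the VCF are missing for every sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    by_site = {(e.chromosome, e.position): e for e in panel}
    data = pd.DataFrame(
        np.full((len(samples), len(panel)), MISSING, dtype=np.int8),
        index=pd.Index(samples, name="subject_id"),
        columns=panel.rsids,
    )
    for rec in vcf:
        key = (rec.CHROM.removeprefix("chr"), rec.POS)
        entry = by_site.get(key)
        if entry is None:
            continue
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record at %s:%d", *key)
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        ea, oa = entry.effect_allele, entry.other_allele
        if (ref, alt) == (oa, ea):
            flip = False
        elif (ref, alt) == (ea, oa):
            flip = True
        else:
            logger.warning(
                "allele pair %s/%s at %s:%d inconsistent with panel %s/%s; site skipped",
                ref, alt, *key, ea, oa,
            )
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown
        counts = rec.gt_types.astype(np.int8)
        counts[counts == 3] = MISSING
        called = counts != MISSING
        if flip:
            counts[called] = 2 - counts[called]
        data[entry.rsid] = counts
    return data


def call_rate(subject: Subject | np.ndarray, panel: PanelTable) -> tuple[float, int]:
    """Per-subject genotyping call rate: (fraction called, count called)."""
    geno = subject.genotypes if isinstance(subject, Subject) else np.asarray(subject)
    if geno.shape[0] != len(panel):
        raise ValueError("genotype vector length differs from panel size")
    n_called = int((geno != MISSING).sum())
    return n_called / len(panel), n_called


def filter_by_call_rate(cohort: Cohort, min_called: int = 8) -> tuple[Cohort, pd.DataFrame]:
    """Drop subjects with fewer than ``min_called`` called panel SNPs.

    Returns the retained cohort and an exclusion log (subject_id,
    status, n_called) listing every dropped subject.  Idempotent.
    """
    if not (0 <= min_called <= len(cohort.panel)):
        raise ValueError("min_called must lie in 0..panel size")
    n_called = (cohort.genotypes != MISSING).sum(axis=1)
    keep = n_called >= min_called
    excluded = pd.DataFrame(
        {
            "status": cohort.phenotypes.loc[~keep, "status"],
            "n_called": n_called[~keep].astype(int),
        }
    )
    if len(excluded):
        logger.info(
            "call-rate filter (<%d called): excluded %d cases, %d controls",
            min_called,
            int((excluded["status"] == "case").sum()),
            int((excluded["status"] == "control").sum()),
        )
    return cohort.select(keep), excluded


def _stratum_mask(cohort: Cohort, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=cohort.phenotypes.index)
    if stratum in ("cases", "case"):
        return cohort.phenotypes["status"] == "case"
    if stratum in ("controls", "control"):
        return cohort.phenotypes["status"] == "control"
    raise ValueError(f"unknown stratum {stratum!r}")


def genotype_counts(cohort: Cohort, rsid: str, stratum: str = "all") -> tuple[int, int, int]:
    """(hom other-allele, het, hom effect-allele) counts among called calls."""
    g = cohort.genotypes.loc[_stratum_mask(cohort, stratum), rsid]
    g = g[g != MISSING]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def minor_allele_frequency(cohort: Cohort, rsid: str, stratum: str = "all") -> float:
    """Frequency of the less-common allele among called genotypes.

    A tie at 0.5 counts the panel's other allele as minor, so that the
    reported MAF always refers to a definite allele.
    """
    n0, n1, n2 = genotype_counts(cohort, rsid, stratum)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError(f"no called genotypes for {rsid} in stratum {stratum!r}")
    ea_freq = (2 * n2 + n1) / (2 * n)
    return min(ea_freq, 1.0 - ea_freq)


def minor_allele_is_effect(cohort: Cohort, rsid: str, stratum: str = "controls") -> bool:
    """Whether the minor allele (in ``stratum``) is the effect allele.

    The 0.5 tie resolves to the panel's other allele as minor.
    """
    n0, n1, n2 = genotype_counts(cohort, rsid, stratum)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError(f"no called genotypes for {rsid} in stratum {stratum!r}")
    ea_freq = (2 * n2 + n1) / (2 * n)
    return ea_freq < 0.5


def duplicate_concordance(cohort: Cohort, pairs: list[tuple[str, str]]) -> float:
    """Genotype concordance over duplicated-sample pairs.

    Pools every SNP where both members of a pair are called and returns
    the fraction of those comparisons that agree.
    """
    agree = total = 0
    for a, b in pairs:
        ga = cohort.genotypes.loc[a].to_numpy()
        gb = cohort.genotypes.loc[b].to_numpy()
        comparable = (ga != MISSING) & (gb != MISSING)
        total += int(comparable.sum())
        agree += int((ga[comparable] == gb[comparable]).sum())
    if total == 0:
        raise ValueError("no comparable genotype calls among the duplicate pairs")
    return agree / total


def hwe_control_report(cohort: Cohort, method: str = "exact") -> pd.DataFrame:
    """Per-SNP Hardy–Weinberg p-values in controls.

    Columns: genotype counts, control MAF and the HWE p-value
    (``method`` = ``"exact"`` or ``"chisq"``).
    """
    test = {"exact": hwe_exact_test, "chisq": hwe_chisq_test}[method]
    rows = []
    for e in cohort.panel:
        n0, n1, n2 = genotype_counts(cohort, e.rsid, "controls")
        if n0 + n1 + n2 == 0:
            rows.append((e.rsid, n0, n1, n2, np.nan, np.nan))
            continue
        rows.append(
            (
                e.rsid,
                n0,
                n1,
                n2,
                minor_allele_frequency(cohort, e.rsid, "controls"),
                test(n0, n1, n2),
            )
        )
    return pd.DataFrame(
        rows, columns=["rsid", "n_hom_other", "n_het", "n_hom_effect", "maf_controls", "hwe_p"]
    ).set_index("rsid")
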