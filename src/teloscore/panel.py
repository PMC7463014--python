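"""The fixed 11-SNP leukocyte-telomere-length panel.

Each panel SNP was discovered by GWAS of leukocyte telomere length (LTL).
The *effect allele* (EA) is the allele associated with longer telomeres;
its per-copy effect is stored both in standard-deviation units (``beta``)
and in base pairs (``bp_per_allele``).  Across the panel the two columns
are related by a single conversion factor of 1200 bp per SD, which
:func:`bp_from_beta` applies.

The panel constants are embedded verbatim (GRCh37 coordinates, 1-based);
they are data, not something this package estimates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterator

__all__ = [
    "SnpDefinition",
    "PanelTable",
    "BP_PER_SD",
    "bp_from_beta",
    "builtin_panel",
    "validate_panel",
    "write_panel_tsv",
    "read_panel_tsv",
]

#: Base pairs of telomere length per standard deviation of the discovery
#: GWAS scale; the single multiplier consistent with every builtin row.
BP_PER_SD = 1200.0


@dataclass(frozen=True)
class SnpDefinition:
    """One panel SNP with its long-telomere effect allele and weights.

    Attributes
    ----------
    rsid : str
        dbSNP identifier.
    gene : str
        Nearest / candidate gene symbol.
    chromosome : str
        Chromosome label (GRCh37).
    position : int
        1-based coordinate (GRCh37).
    effect_allele, other_allele : str
        EA is the allele associated with longer telomeres.
    eaf : float
        Effect-allele frequency in the reference (European) population.
    beta, beta_se : float
        Per-EA-copy LTL effect and its standard error, in SD units.
    bp_per_allele : float
        Per-EA-copy LTL effect in base pairs (``beta * 1200``).
    discovery_pvalue : float
    discovery_study : str
    """

    rsid: str
    gene: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    beta_se: float
    bp_per_allele: float
    discovery_pvalue: float
    discovery_study: str


class PanelTable:
    """Ordered, rsid-keyed collection of :class:`SnpDefinition`."""

    def __init__(self, entries: list[SnpDefinition]):
        rsids = [e.rsid for e in entries]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in panel")
        self._entries = list(entries)
        self._by_rsid = {e.rsid: e for e in entries}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[SnpDefinition]:
        return iter(self._entries)

    def __getitem__(self, rsid: str) -> SnpDefinition:
        return self._by_rsid[rsid]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def __eq__(self, other) -> bool:
        return isinstance(other, PanelTable) and self._entries == other._entries

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self._entries]

    @property
    def bp_weights(self) -> list[float]:
        return [e.bp_per_allele for e in self._entries]

    def subset(self, rsids: list[str]) -> "PanelTable":
        """Panel restricted to ``rsids``, keeping this panel's order."""
        keep = set(rsids)
        missing = keep - set(self.rsids)
        if missing:
            raise KeyError(f"rsids not in panel: {sorted(missing)}")
        return PanelTable([e for e in self._entries if e.rsid in keep])

    def drop(self, rsids: list[str]) -> "PanelTable":
        """Panel with ``rsids`` removed (leave-one-out variants)."""
        drop = set(rsids)
        missing = drop - set(self.rsids)
        if missing:
            raise KeyError(f"rsids not in panel: {sorted(missing)}")
        kept = [e for e in self._entries if e.rsid not in drop]
        if not kept:
            raise ValueError("exclusion leaves an empty panel")
        return PanelTable(kept)


# rsid, gene, chr, pos, EA, OA, EAF, beta, SE, bp, discovery P, study
_PANEL_ROWS = [
    ("rs412658", "ZNF676", "19", 22359440, "T", "C", 0.35, 0.086, 0.010, 103.2, 1.00e-8, "Mangino"),
    ("rs8105767", "ZNF208", "19", 22032639, "G", "A", 0.28, 0.064, 0.011, 76.8, 1.11e-9, "Codd"),
    ("rs3027234", "CTC1", "17", 8232774, "C", "T", 0.78, 0.103, 0.012, 123.6, 2.00e-8, "Mangino"),
    ("rs9420907", "OBFC1", "10", 103916707, "C", "A", 0.13, 0.142, 0.014, 170.4, 7.00e-11, "Levy"),
    ("rs755017", "ZBTB46", "20", 62421622, "G", "A", 0.12, 0.019, 0.013, 22.8, 6.71e-9, "Codd"),
    ("rs6028466", "DHX35", "20", 39500359, "A", "G", 0.07, 0.058, 0.013, 69.6, 2.57e-8, "Haycock"),
    ("rs7675998", "NAF1", "4", 163086668, "G", "A", 0.76, 0.048, 0.012, 57.6, 4.35e-16, "Codd"),
    ("rs10936599", "TERC", "3", 169774313, "C", "T", 0.76, 0.100, 0.011, 120.0, 3.00e-31, "Codd"),
    ("rs11125529", "ACYP2", "2", 54248729, "A", "C", 0.11, 0.065, 0.012, 78.0, 8.00e-10, "Codd"),
    ("rs6772228", "PXK", "3", 58390292, "T", "A", 0.96, 0.041, 0.014, 49.2, 3.91e-10, "Haycock"),
    ("rs2736100", "TERT", "5", 1286401, "C", "A", 0.50, 0.085, 0.013, 102.0, 4.38e-19, "Codd"),
]


def bp_from_beta(beta: float) -> float:
    """Convert an SD-scale LTL effect to base pairs (``beta * 1200``)."""
    return beta * BP_PER_SD


def builtin_panel() -> PanelTable:
    """The 11-SNP LTL panel with published weights.

    Deterministic and side-effect free; two calls compare equal.
    """
    return PanelTable([SnpDefinition(*row) for row in _PANEL_ROWS])


def validate_panel(panel: PanelTable) -> list[str]:
    """Check panel invariants; return one message per violation.

    Checks: EAF strictly inside (0, 1); distinct alleles; non-negative
    beta (weights are oriented to the long-telomere allele); and the
    bp weight consistent with ``beta * 1200`` to within 0.05 bp.
    """
    issues: list[str] = []
    for e in panel:
        if not (0.0 < e.eaf < 1.0):
            issues.append(f"{e.rsid}: eaf out of range ({e.eaf})")
        if e.effect_allele == e.other_allele:
            issues.append(f"{e.rsid}: effect and other allele identical")
        if e.beta < 0:
            issues.append(f"{e.rsid}: negative beta ({e.beta})")
        if abs(e.bp_per_allele - bp_from_beta(e.beta)) > 0.05:
            issues.append(
                f"{e.rsid}: weight inconsistent "
                f"(bp {e.bp_per_allele} vs beta*1200 = {bp_from_beta(e.beta):.1f})"
            )
    return issues


_TSV_COLUMNS = [f.name for f in fields(SnpDefinition)]


def write_panel_tsv(panel: PanelTable, path: str | Path) -> None:
    """Export the panel as a header-bearing TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_COLUMNS)
        for e in panel:
            w.writerow([getattr(e, c) for c in _TSV_COLUMNS])


def read_panel_tsv(path: str | Path) -> PanelTable:
    """Read a panel TSV written by :func:`write_panel_tsv`."""
    entries = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(r.fieldnames or [])
        if missing:
            raise ValueError(f"panel file missing columns: {sorted(missing)}")
        for row in r:
            entries.append(
                SnpDefinition(
                    rsid=row["rsid"],
                    gene=row["gene"],
                    chromosome=row["chromosome"],
                    position=int(row["position"]),
                    effect_allele=row["effect_allele"],
                    other_allele=row["other_allele"],
                    eaf=float(row["eaf"]),
                    beta=float(row["beta"]),
                    beta_se=float(row["beta_se"]),
                    bp_per_allele=float(row["bp_per_allele"]),
                    discovery_pvalue=float(row["discovery_pvalue"]),
                    discovery_study=row["discovery_study"],
                )
            )
    return PanelTable(entries)
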