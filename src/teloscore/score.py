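"""Teloscore computation and control-based quintile binning.

The teloscore is a weighted polygenic proxy for leukocyte telomere
length: for each panel SNP the count of long-telomere alleles (0/1/2) is
multiplied by that SNP's per-allele effect in base pairs, and the
products are summed.  The *raw* score is defined only for subjects with
every panel SNP called; the *scaled* score divides the sum over called
SNPs by the number of called genotypes, so partially genotyped subjects
remain scoreable on a per-genotype-bp scale.

Risk strata are quintiles of the control score distribution: cutpoints
are the 20/40/60/80th percentiles of control scores (linear-interpolation
percentile definition) and every subject — case or control — is binned
against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort, Subject
from .panel import PanelTable

__all__ = [
    "TeloscoreResult",
    "QuintileCutpoints",
    "teloscore",
    "scaled_teloscore",
    "leave_out_score",
    "cohort_scores",
    "control_quintile_cutpoints",
    "assign_quintile",
    "score_table",
]


class IncompleteGenotypeError(ValueError):
    """Raised when a score needs genotype calls that are missing."""


@dataclass(frozen=True)
class TeloscoreResult:
    """Scores for one subject.

    ``raw_score`` (bp) is present only when all panel SNPs are called;
    ``scaled_score`` (bp per called genotype) is always defined when at
    least one SNP is called and equals ``raw_score / panel size`` for
    fully called subjects.
    """

    subject_id: str
    n_called: int
    scaled_score: float
    raw_score: float | None = None


@dataclass(frozen=True)
class QuintileCutpoints:
    """Four ascending control-score thresholds bounding bins 1..5."""

    thresholds: tuple[float, float, float, float]

    def __post_init__(self):
        t = self.thresholds
        if len(t) != 4 or any(a > b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be 4 non-decreasing values")


def _genotype_vector(subject: Subject | np.ndarray) -> np.ndarray:
    g = subject.genotypes if isinstance(subject, Subject) else np.asarray(subject)
    return g.astype(np.int64)


def teloscore(subject: Subject | np.ndarray, panel: PanelTable) -> float:
    """Raw teloscore in bp; requires every panel SNP called."""
    g = _genotype_vector(subject)
    if g.shape[0] != len(panel):
        raise ValueError("genotype vector length differs from panel size")
    if np.any(g == MISSING):
        raise IncompleteGenotypeError(
            "raw teloscore undefined with missing genotypes; use scaled_teloscore"
        )
    return float(g @ np.asarray(panel.bp_weights))


def scaled_teloscore(subject: Subject | np.ndarray, panel: PanelTable) -> TeloscoreResult:
    """Scaled teloscore: bp sum over called SNPs / number called."""
    g = _genotype_vector(subject)
    if g.shape[0] != len(panel):
        raise ValueError("genotype vector length differs from panel size")
    called = g != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise IncompleteGenotypeError("no called genotypes; scaled teloscore undefined")
    weights = np.asarray(panel.bp_weights)
    total = float(g[called] @ weights[called])
    subject_id = subject.subject_id if isinstance(subject, Subject) else ""
    return TeloscoreResult(
        subject_id=subject_id,
        n_called=n_called,
        scaled_score=total / n_called,
        raw_score=total if n_called == len(panel) else None,
    )


def leave_out_score(
    subject: Subject | np.ndarray, panel: PanelTable, excluded_rsids: list[str]
) -> TeloscoreResult:
    """Scaled teloscore over the panel minus ``excluded_rsids``.

    Used for leave-one-out sensitivity runs (e.g. dropping TERT to test
    whether it alone drives the score association).
    """
    if not excluded_rsids:
        return scaled_teloscore(subject, panel)
    reduced = panel.drop(excluded_rsids)  # raises if nothing remains
    keep = [i for i, r in enumerate(panel.rsids) if r not in set(excluded_rsids)]
    g = _genotype_vector(subject)[keep]
    if isinstance(subject, Subject):
        subject = Subject(**{**subject.__dict__, "genotypes": g.astype(np.int8)})
        return scaled_teloscore(subject, reduced)
    return scaled_teloscore(g, reduced)


def cohort_scores(cohort: Cohort, excluded_rsids: list[str] | None = None) -> pd.DataFrame:
    """Vectorised scores for every subject.

    Returns a DataFrame indexed by subject_id with ``n_called``,
    ``raw_score`` (NaN when any genotype is missing) and
    ``scaled_score`` (NaN when no genotype is called).
    """
    panel = cohort.panel
    rsids = panel.rsids
    if excluded_rsids:
        panel = panel.drop(list(excluded_rsids))
        rsids = panel.rsids
    g = cohort.genotypes[rsids].to_numpy(dtype=np.int64)
    called = g != MISSING
    n_called = called.sum(axis=1)
    weights = np.asarray(panel.bp_weights)
    total = np.where(called, g, 0) @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(n_called > 0, total / np.maximum(n_called, 1), np.nan)
    raw = np.where(n_called == len(panel), total, np.nan)
    return pd.DataFrame(
        {"n_called": n_called, "raw_score": raw, "scaled_score": scaled},
        index=cohort.phenotypes.index,
    )


def control_quintile_cutpoints(control_scores) -> QuintileCutpoints:
    """20/40/60/80th percentiles of the control score distribution.

    Percentiles use linear interpolation between order statistics.
    Requires at least five controls with at least five distinct values.
    """
    scores = np.asarray(pd.Series(control_scores).dropna(), dtype=float)
    if scores.size < 5:
        raise ValueError("need at least 5 control scores for quintile cutpoints")
    if np.unique(scores).size < 5:
        raise ValueError("control score distribution too degenerate for quintiles")
    t = np.percentile(scores, [20, 40, 60, 80], method="linear")
    return QuintileCutpoints(thresholds=tuple(float(x) for x in t))


def assign_quintile(score, cutpoints: QuintileCutpoints):
    """Bin scores into 1..5 against control cutpoints.

    Bins are half-open ``(t_{k-1}, t_k]``: a score equal to a threshold
    falls in the lower bin.  Accepts a scalar or an array; NaN maps to 0.
    """
    t = np.asarray(cutpoints.thresholds)
    s = np.asarray(score, dtype=float)
    bins = np.searchsorted(t, s, side="left") + 1
    bins = np.where(np.isnan(s), 0, bins)
    if np.isscalar(score) or s.ndim == 0:
        return int(bins)
    return bins.astype(int)


def score_table(
    cohort: Cohort, cutpoints: QuintileCutpoints | None = None, excluded_rsids=None
) -> pd.DataFrame:
    """Per-subject score report: n_called, raw, scaled, quintile."""
    tab = cohort_scores(cohort, excluded_rsids)
    if cutpoints is None:
        cutpoints = control_quintile_cutpoints(
            tab.loc[~cohort.is_case, "scaled_score"]
        )
    tab["quintile"] = assign_quintile(tab["scaled_score"].to_numpy(), cutpoints)
    return tab
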