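"""Genotyping quality-control statistics.

Hardy–Weinberg equilibrium is tested with the exact conditional
(Levene–Haldane) test: conditional on the observed allele counts, the
number of heterozygotes ``h`` among ``n`` diploids follows

    P(h) = 2^h * n! / (n_AA! * h! * n_aa!) * n_A! * n_a! / (2n)!

and the two-sided p-value sums P(h') over every attainable heterozygote
count whose probability does not exceed that of the observed
configuration.  The chi-square test (1 df) is offered as an option but
the exact test is the default at panel-typical minor-allele frequencies.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = ["hwe_exact_test", "hwe_chisq_test"]


def _log_hwe_prob(n_het: np.ndarray, n_rare: int, n: int) -> np.ndarray:
    """Log conditional probability of each heterozygote count.

    ``n_rare`` is the count of the rarer allele, ``n`` the number of
    diploids; homozygote counts are implied by ``n_het``.
    """
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    n_common = 2 * n - n_rare
    return (
        n_het * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_hom_common + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_rare + 1)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value.

    Parameters are the three genotype counts (either homozygote may be
    passed first; the test is symmetric in the allele labels).

    Raises
    ------
    ValueError
        If any count is negative or all counts are zero.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped subject required")

    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    # attainable heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = _log_hwe_prob(hets, n_rare, n)
    obs = _log_hwe_prob(np.array([n_het]), n_rare, n)[0]
    # tolerance guards ties against floating-point noise
    p = float(np.exp(logp[logp <= obs + 1e-10]).sum())
    return min(p, 1.0)


def hwe_chisq_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree-of-freedom chi-square Hardy–Weinberg test p-value."""
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped subject required")
    f = (2 * n_hom_alt + n_het) / (2 * n)
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    if np.any(expected == 0):
        return 1.0
    stat = float(((np.array(counts) - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))
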