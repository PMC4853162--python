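"""Genotype summaries, Hardy-Weinberg tests, and genetic-model coding.

The locus is a biallelic SNP with alleles A and G; G is treated throughout
as the risk/effect allele.  Genotypes are the strings ``"AA"``, ``"AG"``,
``"GG"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
from scipy import stats

from .errors import DataError, DegenerateTestError

GENOTYPES = ("AA", "AG", "GG")

#: Sentinel returned by :func:`code_genotype` for subjects dropped by the
#: homozygote-contrast coding (heterozygotes).
EXCLUDE = None


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotypes in a sample."""

    n_AA: int
    n_AG: int
    n_GG: int

    def __post_init__(self):
        if min(self.n_AA, self.n_AG, self.n_GG) < 0:
            raise DataError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_AG + self.n_GG

    @classmethod
    def from_labels(cls, genotypes) -> "GenotypeCounts":
        arr = np.asarray(genotypes)
        counts = {g: int(np.sum(arr == g)) for g in GENOTYPES}
        bad = set(np.unique(arr)) - set(GENOTYPES)
        if bad:
            raise DataError(f"unknown genotype labels: {sorted(bad)}")
        return cls(counts["AA"], counts["AG"], counts["GG"])


@dataclass(frozen=True)
class HweResult:
    """Result of a Hardy-Weinberg equilibrium test."""

    chi2: float
    df: int
    p: float
    method: str


def allele_freq(counts: GenotypeCounts) -> float:
    """Sample frequency of the G allele: (2 n_GG + n_AG) / (2 n)."""
    if counts.total == 0:
        raise DataError("cannot compute allele frequency of an empty sample")
    return (2 * counts.n_GG + counts.n_AG) / (2 * counts.total)


def hwe_chisq(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df = 1).

    Expected counts are n*(1-q)^2, 2nq(1-q), nq^2 with q the sample G
    frequency.  No continuity correction is applied.  Raises
    DegenerateTestError for a monomorphic sample, where the expected
    heterozygote count is zero and the statistic is undefined.
    """
    n = counts.total
    if n == 0:
        raise DataError("empty genotype sample")
    q = allele_freq(counts)
    if q == 0.0 or q == 1.0:
        raise DegenerateTestError("monomorphic sample: HWE test undefined")
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    observed = np.array([counts.n_AA, counts.n_AG, counts.n_GG], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, df=1, p=p, method="chi_square")


def _log_het_prob(n_ab: int, n: int, n_a: int) -> float:
    """Log probability of n_ab heterozygotes given n subjects, n_a copies
    of the rarer allele (conditional distribution under HWE)."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_ab) // 2
    n_bb = n - n_aa - n_ab
    return (
        lgamma(n + 1)
        - lgamma(n_aa + 1)
        - lgamma(n_ab + 1)
        - lgamma(n_bb + 1)
        + n_ab * log(2.0)
        + lgamma(n_a + 1)
        + lgamma(n_b + 1)
        - lgamma(2 * n + 1)
    )


def hwe_exact(counts: GenotypeCounts) -> HweResult:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one — the
    standard exact SNP-HWE formulation.  The reported ``chi2`` field holds
    the plain chi-square statistic for reference; ``p`` is exact.
    """
    n = counts.total
    if n == 0:
        raise DataError("empty genotype sample")
    # work with the rarer allele so n_a <= n
    n_g = 2 * counts.n_GG + counts.n_AG
    n_a_allele = 2 * counts.n_AA + counts.n_AG
    n_rare = min(n_g, n_a_allele)
    obs_het = counts.n_AG
    if n_rare == 0:
        # monomorphic: single attainable configuration
        return HweResult(chi2=0.0, df=1, p=1.0, method="exact")
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logps = np.array([_log_het_prob(int(h), n, n_rare) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    obs_prob = probs[np.searchsorted(hets, obs_het)]
    p = float(np.sum(probs[probs <= obs_prob * (1 + 1e-12)]))
    p = min(p, 1.0)
    try:
        chi2 = hwe_chisq(counts).chi2
    except DegenerateTestError:
        chi2 = 0.0
    return HweResult(chi2=chi2, df=1, p=p, method="exact")


_CODING = {
    "additive": {"AA": 0.0, "AG": 1.0, "GG": 2.0},
    "recessive": {"AA": 0.0, "AG": 0.0, "GG": 1.0},
    "homozygote_contrast": {"AA": 0.0, "AG": EXCLUDE, "GG": 1.0},
}

GENETIC_MODELS = tuple(_CODING)


def code_genotype(genotype: str, model: str):
    """Numeric design code for one genotype under a genetic model.

    additive -> copies of G (0/1/2); recessive -> 1 for GG else 0;
    homozygote_contrast -> AA=0, GG=1, AG excluded (returns
    :data:`EXCLUDE`).
    """
    if model not in _CODING:
        raise DataError(f"unknown genetic model: {model!r}")
    if genotype not in GENOTYPES:
        raise DataError(f"unknown genotype label: {genotype!r}")
    return _CODING[model][genotype]


def code_genotypes(genotypes, model: str) -> np.ndarray:
    """Vectorised :func:`code_genotype`; excluded entries come back as NaN."""
    return np.array(
        [
            np.nan if (c := code_genotype(g, model)) is EXCLUDE else c
            for g in genotypes
        ],
        dtype=float,
    )


def genotype_summary(genotypes_by_group: dict) -> "pd.DataFrame":
    """Counts, proportions, allele frequency and HWE tests per group.

    ``genotypes_by_group`` maps a group label (e.g. ``"control"``) to a
    sequence of genotype labels.  Returns a tidy DataFrame, one row per
    group.
    """
    import pandas as pd

    rows = []
    for group, genos in genotypes_by_group.items():
        c = GenotypeCounts.from_labels(genos)
        row = {
            "group": group,
            "n": c.total,
            "n_AA": c.n_AA,
            "n_AG": c.n_AG,
            "n_GG": c.n_GG,
            "freq_G": allele_freq(c),
        }
        try:
            chisq = hwe_chisq(c)
            row["hwe_chi2"] = chisq.chi2
            row["hwe_p_chisq"] = chisq.p
        except DegenerateTestError:
            row["hwe_chi2"] = np.nan
            row["hwe_p_chisq"] = np.nan
        row["hwe_p_exact"] = hwe_exact(c).p
        rows.append(row)
    return pd.DataFrame(rows)
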