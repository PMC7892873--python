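"""Single-locus case-control association by Fisher's exact test.

Each variant is reduced to a 2×2 table (rows = case/control, columns =
carrier/non-carrier by default, or alt/ref alleles in allelic mode) and
tested with the two-sided Fisher exact test.  The two-sided p-value follows
the probability-mass definition: the sum of hypergeometric probabilities of
every table with the same margins whose probability does not exceed that of
the observed table (with a small relative tolerance to absorb floating-point
ties).  Significance is flagged against the Bonferroni-corrected threshold
alpha / m over the m variants scanned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .io import CohortDesign, GenotypeMatrix, MISSING_DOSAGE, VariantRecord

__all__ = [
    "ContingencyTable2x2",
    "SingleLocusResult",
    "fisher_exact_two_sided",
    "bonferroni_threshold",
    "odds_ratio",
    "carrier_table",
    "allelic_table",
    "single_locus_scan",
]

# Relative tolerance when comparing table probabilities to the observed
# table's probability; absorbs floating-point noise on exact ties.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts a, b / c, d (rows = case, control)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"cell counts must be non-negative integers: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def _log_hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(total n, row1 total r1, col1 total c1)."""
    r2 = n - r1
    return (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the probability-mass method.

    Conditional on the margins, the first cell follows a hypergeometric
    distribution; the p-value sums the probabilities of all tables as or
    less probable than the observed one.  Probabilities are compared with
    relative tolerance 1e-7 so exact rational ties are counted as ties.  An
    empty row or column margin leaves only one table consistent with the
    margins; p is defined as 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn(
            "degenerate 2x2 table (empty margin); p-value defined as 1",
            stacklevel=2,
        )
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, n, r1, c1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[a - lo]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m for m tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, bool]:
    """Odds ratio (ad)/(bc); Haldane 0.5 correction when any cell is 0.

    Returns ``(odds_ratio, corrected)``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


@dataclass
class SingleLocusResult:
    variant_key: str
    table: ContingencyTable2x2
    p_value: float
    threshold: float
    significant: bool
    odds_ratio: float
    or_corrected: bool


def carrier_table(
    dosages: np.ndarray, y: np.ndarray
) -> ContingencyTable2x2:
    """Case/control × carrier/non-carrier counts over non-missing genotypes."""
    ok = dosages != MISSING_DOSAGE
    carrier = (dosages >= 1) & ok
    a = int(np.sum(carrier & (y == 1)))
    b = int(np.sum(ok & ~carrier & (y == 1)))
    c = int(np.sum(carrier & (y == 0)))
    d = int(np.sum(ok & ~carrier & (y == 0)))
    return ContingencyTable2x2(a, b, c, d)


def allelic_table(dosages: np.ndarray, y: np.ndarray) -> ContingencyTable2x2:
    """Case/control × alt/ref allele counts over non-missing genotypes."""
    ok = dosages != MISSING_DOSAGE
    d_case = dosages[(y == 1) & ok]
    d_ctrl = dosages[(y == 0) & ok]
    a = int(d_case.sum())
    b = int(2 * d_case.size - a)
    c = int(d_ctrl.sum())
    d = int(2 * d_ctrl.size - c)
    return ContingencyTable2x2(a, b, c, d)


def single_locus_scan(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    mode: str = "carrier",
    alpha: float = 0.05,
) -> list[SingleLocusResult]:
    """Per-variant Fisher exact scan with Bonferroni-corrected threshold.

    ``mode='carrier'`` collapses each subject to carrier status;
    ``mode='allelic'`` counts alleles.  The threshold is alpha divided by
    the number of variants scanned, regardless of how many tests return
    p = 1.
    """
    if mode not in ("carrier", "allelic"):
        raise ValueError(f"unknown mode {mode!r}")
    if not variants:
        return []
    y = design.phenotype_vector(genotypes.sample_ids)
    threshold = bonferroni_threshold(alpha, len(variants))
    build = carrier_table if mode == "carrier" else allelic_table
    results = []
    for v in variants:
        dos = genotypes.dosage_vector(v.key)
        table = build(dos, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_two_sided(table)
        orr, corrected = odds_ratio(table)
        results.append(
            SingleLocusResult(
                variant_key=v.key,
                table=table,
                p_value=p,
                threshold=threshold,
                significant=p < threshold,
                odds_ratio=orr,
                or_corrected=corrected,
            )
        )
    return results
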