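"""Morphometry helpers: G-ratio and the variance-gated two-sample t-test.

The G-ratio — diameter of the naked axon divided by the diameter of the
myelinated fibre — is a myelination-thickness index in (0, 1).  Group
comparisons follow the classical gated procedure: a two-sided F-test on the
ratio of sample variances decides between the pooled-variance Student
t-test (variances compatible) and the Welch unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MorphometrySample",
    "GroupComparison",
    "g_ratio",
    "variance_gated_comparison",
]


def g_ratio(naked_diameter: float, myelinated_diameter: float) -> float:
    """naked / myelinated fibre diameter, strictly inside (0, 1).

    Both diameters must be positive and the naked (axonal) diameter must be
    strictly smaller than the myelinated (fibre) diameter — a myelinated
    axon always adds sheath thickness.
    """
    if naked_diameter <= 0 or myelinated_diameter <= 0:
        raise ValueError("diameters must be positive")
    if naked_diameter >= myelinated_diameter:
        raise ValueError(
            f"naked diameter ({naked_diameter}) must be smaller than "
            f"myelinated diameter ({myelinated_diameter})"
        )
    return naked_diameter / myelinated_diameter


@dataclass
class MorphometrySample:
    """Axon measurements for one group (diameters in µm)."""

    axon_diameters: list[float] = field(default_factory=list)
    g_ratio_pairs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.axon_diameters):
            raise ValueError("axon diameters must be positive")
        for naked, myelinated in self.g_ratio_pairs:
            g_ratio(naked, myelinated)  # validates

    def g_ratios(self) -> list[float]:
        return [g_ratio(nk, my) for nk, my in self.g_ratio_pairs]

    def mean_g_ratio(self) -> float:
        values = self.g_ratios()
        if not values:
            raise ValueError("no G-ratio pairs")
        return float(np.mean(values))


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    variance_test_p: float
    chosen_test: str  # "student" | "welch"
    p_value: float
    alpha: float = 0.05


def variance_gated_comparison(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha_var: float = 0.05,
) -> GroupComparison:
    """Two-sample comparison gated on a two-sided variance-ratio F-test.

    The F statistic is the ratio of the two sample variances (unbiased,
    ddof 1); its two-sided p-value is twice the smaller tail of the F
    distribution.  If that p-value is >= ``alpha_var`` the variances are
    treated as homogeneous and the pooled-variance Student t-test is used;
    otherwise the Welch t-test.  Both t-tests are two-sided.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 or var_b == 0:
        raise ValueError("zero variance in a sample; the F gate is undefined")
    f = var_a / var_b
    dfa, dfb = a.size - 1, b.size - 1
    p_f = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    p_f = min(p_f, 1.0)
    equal_var = p_f >= alpha_var
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        variance_test_p=float(p_f),
        chosen_test="student" if equal_var else "welch",
        p_value=float(t_res.pvalue),
        alpha=alpha_var,
    )
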