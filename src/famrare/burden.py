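"""Gene-based rare-variant burden testing.

A gene's rare, functionally deleterious variants are combined into one
test of case-control enrichment, restoring power that single-variant tests
lack at these frequencies.  Three complementary statistics are provided:

* **CMC** — carrier collapsing: a subject is a carrier if it holds at
  least one rare allele in the gene; carrier proportions are compared with
  the two-sided Fisher exact test (the rare-variant-only degenerate case of
  the combined multivariate and collapsing framework).
* **Madsen–Browning** — a weighted-sum test: dosages are weighted by
  ``1 / sqrt(n_j q_j (1 - q_j))`` with ``q_j`` the allele frequency
  estimated in unaffected subjects with a +1 pseudo-count, subjects are
  scored by their weighted allele sum, and the sum of case ranks is
  referred to its label-permutation distribution (one-sided toward case
  excess).
* **SKAT-O** — the optimal unified test; see :mod:`famrare.skato`.

Before testing, QC removes variants that are common in any public database
or the in-house panel (AF > 0.005, strict), masks genotypes below the
quality floor, and drops variants whose post-masking call rate falls below
90%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

from .association import ContingencyTable2x2, bonferroni_threshold, fisher_exact_two_sided
from .io import CohortDesign, GenotypeMatrix, MISSING_DOSAGE, VariantRecord
from .skato import DEFAULT_RHO_GRID, SkatOResult, skat_o

__all__ = [
    "BurdenQCConfig",
    "GeneBurdenResult",
    "WeightScheme",
    "qc_filter",
    "collapse_carriers",
    "cmc_test",
    "madsen_browning_test",
    "skat_o_test",
    "gene_burden_report",
]


@dataclass
class BurdenQCConfig:
    """QC thresholds applied before burden testing.

    ``af_threshold`` — exclude variants with AF strictly above this in any
    public source or the in-house panel; ``min_call_rate`` — exclude
    variants with call rate strictly below this after quality masking;
    ``min_genotype_quality`` — genotypes with quality strictly below this
    are set to missing (genotypes without a quality value are kept).
    """

    af_threshold: float = 0.005
    min_call_rate: float = 0.90
    min_genotype_quality: float = 99.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_threshold <= 1.0:
            raise ValueError("af_threshold must lie in [0,1]")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must lie in [0,1]")
        if self.min_genotype_quality < 0:
            raise ValueError("min_genotype_quality must be >= 0")


@dataclass
class WeightScheme:
    """Per-variant weighting for score-based burden statistics.

    ``beta_1_25`` (default) — Beta(1, 25) density evaluated at the pooled
    sample MAF, up-weighting the rarest variants; ``madsen_browning`` —
    inverse allele-frequency standard deviation estimated in unaffected
    subjects; ``uniform`` — equal weights.
    """

    kind: str = "beta_1_25"
    beta_a: float = 1.0
    beta_b: float = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("beta_1_25", "madsen_browning", "uniform"):
            raise ValueError(f"unknown weight scheme {self.kind!r}")

    def compute(self, dosages: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Weights for an n × m dosage matrix (negative entries = missing)."""
        g = np.asarray(dosages, dtype=float)
        miss = g < 0
        if self.kind == "uniform":
            return np.ones(g.shape[1])
        if self.kind == "beta_1_25":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-missing columns
                maf = np.nanmean(np.where(miss, np.nan, g), axis=0) / 2.0
            maf = np.nan_to_num(maf, nan=0.0)
            return beta_dist.pdf(np.clip(maf, 0.0, 1.0), self.beta_a, self.beta_b)
        return _madsen_browning_weights(g, np.asarray(y))


def _madsen_browning_weights(g: np.ndarray, y: np.ndarray) -> np.ndarray:
    """w_j = 1 / sqrt(n_j q_j (1 - q_j)), q_j from unaffected with +1 count."""
    miss = g < 0
    ctrl = y == 0
    alt_u = np.where(miss[ctrl], 0, g[ctrl]).sum(axis=0)
    n_u = (~miss[ctrl]).sum(axis=0)
    q = (alt_u + 1.0) / (2.0 * n_u + 2.0)
    n_j = (~miss).sum(axis=0)
    return 1.0 / np.sqrt(np.maximum(n_j, 1) * q * (1.0 - q))


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    config: BurdenQCConfig | None = None,
    inhouse_af: Mapping[str, float] | None = None,
) -> tuple[list[VariantRecord], GenotypeMatrix, pd.DataFrame]:
    """Quality-control filter for burden testing.

    Genotypes with quality below ``min_genotype_quality`` are masked to
    missing first; call rates are computed on the masked matrix.  A variant
    is excluded when its AF exceeds ``af_threshold`` in any public source
    or in the in-house panel (reason ``"af"``), or when its masked call
    rate drops below ``min_call_rate`` (reason ``"call_rate"``).  Returns
    the retained records, the masked matrix (all variants, masking applied)
    and an exclusion log.
    """
    config = config or BurdenQCConfig()
    inhouse_af = inhouse_af or {}
    masked = genotypes.copy()
    if masked.genotype_quality is not None:
        low = masked.genotype_quality < config.min_genotype_quality
        masked.dosages[low] = MISSING_DOSAGE
    retained: list[VariantRecord] = []
    log_rows: list[tuple[str, str]] = []
    for v in variants:
        if (
            v.max_af() > config.af_threshold
            or inhouse_af.get(v.key, 0.0) > config.af_threshold
        ):
            log_rows.append((v.key, "af"))
            continue
        if masked.call_rate(v.key) < config.min_call_rate:
            log_rows.append((v.key, "call_rate"))
            continue
        retained.append(v)
    log = pd.DataFrame(log_rows, columns=["variant_key", "reason"])
    return retained, masked, log


# ---------------------------------------------------------------------------
# Collapsing and tests


def _round_half_up_pct(count: int, n: int) -> float:
    """100 * count / n rounded half-up to 2 decimals (report formatting)."""
    if n == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def collapse_carriers(
    gene: str,
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
) -> tuple[int, int, float, float]:
    """Carrier counts and percent frequencies for one gene.

    A subject counts as a carrier when it holds at least one alternate
    allele across the gene's retained variants (missing genotypes do not
    contribute).  Frequencies are percentages of the full cohort sizes,
    rounded half-up to two decimals.
    """
    keys = [v.key for v in variants if v.gene == gene]
    if not keys:
        warnings.warn(f"no retained variants in gene {gene}", stacklevel=2)
        return 0, 0, 0.0, 0.0
    sub = genotypes.subset_variants(keys)
    carrier = (sub.dosages > 0).any(axis=1)
    idx = {s: i for i, s in enumerate(sub.sample_ids)}
    case_count = int(sum(carrier[idx[s]] for s in design.case_ids if s in idx))
    control_count = int(sum(carrier[idx[s]] for s in design.control_ids if s in idx))
    return (
        case_count,
        control_count,
        _round_half_up_pct(case_count, design.n_cases),
        _round_half_up_pct(control_count, design.n_controls),
    )


def cmc_test(case_count: int, control_count: int, design: CohortDesign) -> float:
    """Collapsing test: Fisher exact on the carrier × status table."""
    table = ContingencyTable2x2(
        case_count,
        design.n_cases - case_count,
        control_count,
        design.n_controls - control_count,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fisher_exact_two_sided(table)


def madsen_browning_test(
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    n_permutations: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """Weighted-sum rank test with permutation p-value.

    Subjects are scored by ``sum_j w_j * dosage_ij`` with unaffected-based
    inverse-frequency weights; the statistic is the sum of case ranks of
    the scores.  The p-value is one-sided toward case excess:
    ``(1 + #{permuted >= observed}) / (1 + B)`` over B random label
    permutations, or the exact proportion over every case/control label
    assignment when ``exhaustive=True`` (feasible for small cohorts only).
    Missing dosages contribute no alleles to the score.
    """
    if not exhaustive and n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    y = design.phenotype_vector(genotypes.sample_ids)
    g = genotypes.dosages.astype(float)
    g[g < 0] = 0.0
    w = _madsen_browning_weights(genotypes.dosages.astype(float), y)
    scores = g @ w
    if np.allclose(scores, scores[0]):
        return 1.0
    ranks = rankdata(scores)
    n, k = len(y), int(y.sum())
    observed = float(ranks[y == 1].sum())

    if exhaustive:
        total = comb(n, k)
        if total > 500_000:
            raise ValueError(
                f"exhaustive enumeration infeasible: C({n},{k}) = {total}"
            )
        hits = sum(
            1
            for case_idx in combinations(range(n), k)
            if ranks[list(case_idx)].sum() >= observed
        )
        return hits / total

    rng = np.random.default_rng(seed)
    b = int(n_permutations)
    # Random k-subsets via argpartition of iid uniforms (uniform over subsets).
    draws = rng.random((b, n))
    subsets = np.argpartition(draws, k - 1, axis=1)[:, :k]
    permuted = ranks[subsets].sum(axis=1)
    return float((1.0 + np.sum(permuted >= observed)) / (1.0 + b))


def skat_o_test(
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    weights: WeightScheme | None = None,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
    p_method: str = "moment_matching",
    n_permutations: int = 9999,
    seed: int = 0,
) -> SkatOResult:
    """SKAT-O over a gene's retained variants (see :mod:`famrare.skato`)."""
    weights = weights or WeightScheme()
    y = design.phenotype_vector(genotypes.sample_ids)
    g = genotypes.dosages.astype(float)
    w = weights.compute(g, y)
    return skat_o(
        g,
        y,
        w,
        rho_grid=rho_grid,
        p_method=p_method,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Report


@dataclass
class GeneBurdenResult:
    """One row of the gene-based burden report."""

    gene: str
    n_variants_tested: int
    case_count: int
    control_count: int
    case_freq_pct: float
    control_freq_pct: float
    p_cmc: float
    p_mb: float
    p_skato: float
    rho_selected: float = 0.0
    threshold: float = 0.05
    significant: bool = field(default=False)


def gene_burden_report(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    genes: Sequence[str] | None = None,
    qc: BurdenQCConfig | None = None,
    inhouse_af: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    weights: WeightScheme | None = None,
    mb_permutations: int = 9999,
    seed: int = 0,
) -> tuple[list[GeneBurdenResult], pd.DataFrame]:
    """QC, collapse and test every gene; return rows and a tidy table.

    ``genes`` defaults to every annotated gene among the input variants.
    Significance per gene is flagged when the smallest of the three
    p-values falls below the Bonferroni threshold alpha / n_genes.  A gene
    left without retained variants after QC gets zero counts and p = 1.
    """
    retained, masked, _log = qc_filter(variants, genotypes, qc, inhouse_af)
    if genes is None:
        genes = sorted({v.gene for v in variants if v.gene})
    threshold = bonferroni_threshold(alpha, len(genes))
    results: list[GeneBurdenResult] = []
    for g_idx, gene in enumerate(genes):
        gene_vars = [v for v in retained if v.gene == gene]
        if not gene_vars:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cc, nc, cf, nf = collapse_carriers(gene, gene_vars, masked, design)
            results.append(
                GeneBurdenResult(gene, 0, 0, 0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, threshold)
            )
            continue
        keys = [v.key for v in gene_vars]
        sub = masked.subset_variants(keys)
        case_count, control_count, case_pct, control_pct = collapse_carriers(
            gene, gene_vars, masked, design
        )
        p_cmc = cmc_test(case_count, control_count, design)
        p_mb = madsen_browning_test(
            sub, design, n_permutations=mb_permutations, seed=seed * 1009 + g_idx
        )
        skato_res = skat_o_test(sub, design, weights=weights, seed=seed * 1013 + g_idx)
        row = GeneBurdenResult(
            gene=gene,
            n_variants_tested=len(gene_vars),
            case_count=case_count,
            control_count=control_count,
            case_freq_pct=case_pct,
            control_freq_pct=control_pct,
            p_cmc=p_cmc,
            p_mb=p_mb,
            p_skato=skato_res.p_value,
            rho_selected=skato_res.rho_selected,
            threshold=threshold,
            significant=min(p_cmc, p_mb, skato_res.p_value) < threshold,
        )
        results.append(row)
    table = pd.DataFrame([r.__dict__ for r in results])
    return results, table
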