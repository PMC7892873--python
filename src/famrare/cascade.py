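"""Family-based variant prioritization funnel.

The cascade narrows an exome's worth of variants to a single candidate in
four stages:

1. **all** — every input variant.
2. **deleterious** — protein-altering functional class (stop-gain,
   stop-loss, nonsynonymous, splice-site) with alternate allele frequency
   ≤ 0.5% in every consulted population database (absence counts as 0).
3. **segregating** — complete cosegregation with affection status under a
   dominant model: every affected genotyped member carries the allele and
   no unaffected member does.
4. **post-control-exclusion** — candidates observed at all in an in-house
   healthy-control screening cohort are removed; a truly family-private,
   fully penetrant allele should be absent from controls.

Stage order never changes the final set (the filters are independent
per-variant predicates); it is fixed here to mirror how such screens are
run, cheapest annotation checks first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DELETERIOUS_CLASSES,
    GenotypeMatrix,
    MISSING_DOSAGE,
    Pedigree,
    VariantRecord,
)

__all__ = [
    "CascadeConfig",
    "CascadeResult",
    "RARITY_CLASSES",
    "is_deleterious",
    "classify_rarity",
    "segregates",
    "control_exclusion",
    "run_cascade",
]

STAGE_NAMES = ("all", "deleterious", "segregating", "post-control-exclusion")

RARITY_CLASSES = ("novel", "ultra-rare", "rare", "common")


def is_deleterious(variant: VariantRecord, af_threshold: float = 0.005) -> bool:
    """Protein-altering class and rare in every consulted database.

    True iff the functional class is stop-gain, stop-loss, nonsynonymous or
    splice-site AND the maximum allele frequency over all sources is
    ``<= af_threshold`` (a variant absent from every source counts as 0, so
    database-novel protein-altering variants pass).  The boundary is
    inclusive: AF exactly at the threshold passes.
    """
    if variant.functional_class not in DELETERIOUS_CLASSES:
        return False
    return variant.max_af() <= af_threshold


def classify_rarity(variant: VariantRecord) -> str:
    """Rarity class from the merged database frequencies.

    novel — absent from every consulted source; ultra-rare — max AF
    < 0.001; rare — max AF < 0.005 (an AF of exactly 0.001 falls here);
    common — otherwise.
    """
    if not variant.af_by_source:
        return "novel"
    max_af = variant.max_af()
    if max_af < 0.001:
        return "ultra-rare"
    if max_af < 0.005:
        return "rare"
    return "common"


def segregates(
    variant_key: str,
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    model: str = "dominant",
    missing_policy: str = "strict",
) -> bool:
    """Complete cosegregation with affection status.

    Under the dominant model a variant segregates iff every affected member
    carries at least one alternate allele (dosage >= 1) and every unaffected
    member carries none.  Members with unknown affection are ignored.  A
    missing dosage fails the variant under ``missing_policy='strict'``
    (default) or is skipped under ``'ignore'``.
    """
    if model != "dominant":
        raise ValueError(f"unsupported segregation model: {model!r}")
    if missing_policy not in ("strict", "ignore"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    genotyped = set(genotypes.sample_ids)
    relevant = [
        m for m in pedigree if m.affection in ("affected", "unaffected")
    ]
    unmatched = [m.individual_id for m in relevant if m.individual_id not in genotyped]
    if unmatched:
        raise KeyError(
            "pedigree members with known affection missing from genotype "
            f"matrix: {unmatched}"
        )
    col = genotypes.dosage_vector(variant_key)
    for m in relevant:
        d = col[genotypes.sample_index(m.individual_id)]
        if d == MISSING_DOSAGE:
            if missing_policy == "strict":
                return False
            continue
        if m.affection == "affected" and d < 1:
            return False
        if m.affection == "unaffected" and d != 0:
            return False
    return True


def control_exclusion(
    variant_key: str, control_genotypes: GenotypeMatrix
) -> tuple[bool, float]:
    """Screen a candidate against an in-house control cohort.

    Returns ``(excluded, control_maf)`` with control MAF = alternate
    alleles / (2 × non-missing genotypes); the variant is excluded iff any
    alternate allele is observed.  A variant absent from the control matrix
    is treated as unobserved (MAF 0, not excluded); an all-missing column
    leaves the MAF undefined (NaN) and does not exclude, with a warning.
    """
    if not control_genotypes.has_variant(variant_key):
        return False, 0.0
    col = control_genotypes.dosage_vector(variant_key)
    observed = col[col != MISSING_DOSAGE]
    if observed.size == 0:
        warnings.warn(
            f"all control genotypes missing for {variant_key}; control MAF "
            "undefined, variant not excluded",
            stacklevel=2,
        )
        return False, float("nan")
    maf = float(observed.sum()) / (2.0 * observed.size)
    return maf > 0.0, maf


@dataclass
class CascadeConfig:
    af_threshold: float = 0.005
    model: str = "dominant"
    missing_policy: str = "strict"


@dataclass
class CascadeResult:
    """Per-stage surviving variant sets plus a per-variant report table."""

    stage_names: tuple[str, ...]
    surviving: dict[str, set[str]]
    report: pd.DataFrame = field(repr=False)

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(self.surviving[s]) for s in self.stage_names}

    @property
    def final_candidates(self) -> set[str]:
        return set(self.surviving[self.stage_names[-1]])

    def funnel(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": list(self.stage_names),
                "count": [len(self.surviving[s]) for s in self.stage_names],
            }
        )


def run_cascade(
    variants: Sequence[VariantRecord],
    family_genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    control_genotypes: GenotypeMatrix | None = None,
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Apply the full prioritization funnel and record per-stage survivors.

    Stages run in order deleterious → segregating → control exclusion; each
    stage only inspects the survivors of the previous one, so the surviving
    sets are nested by construction.  When ``control_genotypes`` is None the
    final stage keeps all segregating candidates (no screening data).
    """
    config = config or CascadeConfig()
    all_keys = [v.key for v in variants]
    if len(set(all_keys)) != len(all_keys):
        raise ValueError("duplicate variant keys in cascade input")

    deleterious = {
        v.key for v in variants if is_deleterious(v, config.af_threshold)
    }
    segregating = {
        key
        for key in deleterious
        if segregates(
            key,
            family_genotypes,
            pedigree,
            model=config.model,
            missing_policy=config.missing_policy,
        )
    }
    control_maf: dict[str, float] = {}
    final = set()
    for key in segregating:
        if control_genotypes is None:
            final.add(key)
            continue
        excluded, maf = control_exclusion(key, control_genotypes)
        control_maf[key] = maf
        if not excluded:
            final.add(key)

    surviving = {
        "all": set(all_keys),
        "deleterious": deleterious,
        "segregating": segregating,
        "post-control-exclusion": final,
    }
    report = pd.DataFrame(
        {
            "variant_key": all_keys,
            "gene": [v.gene for v in variants],
            "functional_class": [v.functional_class for v in variants],
            "max_af": [v.max_af() for v in variants],
            "rarity": [classify_rarity(v) for v in variants],
            "deleterious": [k in deleterious for k in all_keys],
            "segregating": [k in segregating for k in all_keys],
            "control_maf": [control_maf.get(k, np.nan) for k in all_keys],
            "candidate": [k in final for k in all_keys],
        }
    )
    return CascadeResult(STAGE_NAMES, surviving, report)
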