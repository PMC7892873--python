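"""Synthetic pedigree and case-control cohort generator.

The analysis this package implements was designed for (i) a three-generation
multiplex family carrying one fully penetrant dominant candidate variant and
(ii) a targeted-sequencing case-control cohort with rare variants in a
handful of genes.  No genotype data of that kind can be shipped, so this
module generates datasets with the same statistical structure:

* :func:`simulate_family` drops background variants through a pedigree
  (founders at Hardy–Weinberg equilibrium, Mendelian transmission of one
  allele per parent) and plants a dominant variant carried by affected
  members according to a penetrance model.
* :func:`simulate_case_control` draws control genotypes from HWE at each
  variant's population MAF and inflates the per-variant carrier probability
  in cases on the odds scale by a per-gene odds ratio (carrier-based
  enrichment, matching the collapsing tests the cohort is meant to
  exercise).

All randomness flows from one master seed; independent component streams are
derived with fixed ``numpy`` ``SeedSequence`` spawn keys, so results are
reproducible down to byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    MISSING_DOSAGE,
    Pedigree,
    PedigreeMember,
    CohortDesign,
    VariantRecord,
    write_ped,
    write_vcf,
)

__all__ = [
    "SpectrumBin",
    "FamilySimConfig",
    "GeneModel",
    "CohortSimConfig",
    "FamilySimResult",
    "CohortSimResult",
    "default_family_pedigree",
    "default_planted_variant",
    "default_gene_models",
    "simulate_family",
    "simulate_case_control",
    "simulate_null_cohort",
    "simulate_control_panel",
    "transmit_alleles",
    "write_family_dataset",
    "write_cohort_dataset",
]

#: Names of the emulated population allele-frequency databases.
DEFAULT_AF_SOURCES = ("popdb_jpn", "popdb_global")

# Spawn keys for the independent random streams derived from the master seed.
_STREAM_FAMILY = 11
_STREAM_COHORT = 23
_STREAM_CONTROL_PANEL = 37


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SpectrumBin:
    """One point mass of the background allele-frequency spectrum.

    ``in_databases`` — whether variants drawn from this bin are reported by
    the emulated population databases (False models variants that are novel
    to every database while still present in the population).
    """

    weight: float
    af: float
    in_databases: bool = True


#: Common / low-frequency / rare / ultra-rare / database-novel mix used for
#: the exome background when no spectrum is supplied.
DEFAULT_AF_SPECTRUM = (
    SpectrumBin(0.45, 0.10),
    SpectrumBin(0.20, 0.02),
    SpectrumBin(0.15, 0.004),
    SpectrumBin(0.12, 0.0008),
    SpectrumBin(0.08, 0.002, in_databases=False),
)

# Functional-class mix for background variants (exome-like: mostly
# synonymous/nonsynonymous, occasional truncating or splice variants).
_CLASS_MIX = (
    ("synonymous", 0.40),
    ("nonsynonymous", 0.44),
    ("splice-site", 0.05),
    ("stop-gain", 0.04),
    ("stop-loss", 0.01),
    ("other", 0.06),
)


def default_family_pedigree() -> Pedigree:
    """Three-generation multiplex pedigree, 10 genotyped members.

    Seven affected (I-9, II-3, II-5, II-12, II-17, III-2, III-3) and three
    unaffected (I-13, II-11, II-20) members are genotyped; spouses I-10,
    I-14 and II-16 are ungenotyped connectors.  The structure is synthetic:
    it reproduces the generation depth and affected/unaffected counts of a
    dominant multiplex family, not any real family's topology.
    """
    m = PedigreeMember
    members = [
        m("I-9", None, None, "female", "affected"),
        m("I-10", None, None, "male", "unknown"),
        m("I-13", None, None, "male", "unaffected"),
        m("I-14", None, None, "female", "unknown"),
        m("II-3", "I-10", "I-9", "female", "affected"),
        m("II-5", "I-10", "I-9", "male", "affected"),
        m("II-11", "I-10", "I-9", "female", "unaffected"),
        m("II-12", "I-10", "I-9", "male", "affected"),
        m("II-17", "I-10", "I-9", "female", "affected"),
        m("II-20", "I-10", "I-9", "male", "unaffected"),
        m("II-16", "I-13", "I-14", "male", "unknown"),
        m("III-2", "II-16", "II-17", "female", "affected"),
        m("III-3", "II-16", "II-17", "male", "affected"),
    ]
    return Pedigree(members, family_id="FAM1")


#: Members of the default pedigree with genotype data (7 affected, 3 unaffected).
DEFAULT_GENOTYPED = (
    "I-9",
    "I-13",
    "II-3",
    "II-5",
    "II-11",
    "II-12",
    "II-17",
    "II-20",
    "III-2",
    "III-3",
)


def default_planted_variant() -> VariantRecord:
    """The planted fully penetrant candidate: a chromatin-remodeller missense
    variant absent from every emulated database."""
    return VariantRecord(
        chrom="12",
        pos=132064747,
        ref="C",
        alt="T",
        var_id="planted_candidate",
        gene="EP400",
        functional_class="nonsynonymous",
        af_by_source={},
    )


@dataclass
class FamilySimConfig:
    """Configuration of the family simulator.

    ``penetrance_affected`` is the probability an affected member carries
    the planted allele; ``penetrance_unaffected`` the probability an
    unaffected member does *not* carry it.  Both default to 1.0 (complete
    penetrance, no phenocopies), the regime a complete-cosegregation filter
    assumes.
    """

    pedigree: Pedigree = field(default_factory=default_family_pedigree)
    genotyped_ids: tuple[str, ...] = DEFAULT_GENOTYPED
    planted_variant: VariantRecord = field(default_factory=default_planted_variant)
    penetrance_affected: float = 1.0
    penetrance_unaffected: float = 1.0
    n_background: int = 200
    background_af_spectrum: tuple[SpectrumBin, ...] = DEFAULT_AF_SPECTRUM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance_affected <= 1.0:
            raise ValueError("penetrance_affected must lie in [0,1]")
        if not 0.0 <= self.penetrance_unaffected <= 1.0:
            raise ValueError("penetrance_unaffected must lie in [0,1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        total = sum(b.weight for b in self.background_af_spectrum)
        if self.background_af_spectrum and not np.isclose(total, 1.0):
            raise ValueError(f"spectrum weights must sum to 1, got {total}")
        for b in self.background_af_spectrum:
            if not 0.0 < b.af <= 0.5:
                raise ValueError(f"spectrum AF must lie in (0, 0.5], got {b.af}")
        if self.planted_variant.af_by_source:
            raise ValueError("planted variant must be absent from all AF sources")


@dataclass
class FamilySimResult:
    variants: list[VariantRecord]
    genotypes: GenotypeMatrix  # genotyped members only
    pedigree: Pedigree
    truth: pd.DataFrame  # variant_key, role, true_af, in_databases, gene, class
    af_sources: dict[str, dict[str, float]]


def transmit_alleles(parent_dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one transmitted allele (0/1) per parent from diploid dosages.

    Each of the parent's two alleles is passed with probability 1/2, so the
    transmitted allele is Bernoulli(dosage / 2).  Missing dosages transmit
    the reference allele (the family simulator never produces missing
    parental genotypes internally).
    """
    d = np.asarray(parent_dosages, dtype=float)
    d = np.where(d == MISSING_DOSAGE, 0, d)
    return (rng.random(d.shape) < d / 2.0).astype(np.int8)


def _draw_classes(rng: np.random.Generator, n: int) -> list[str]:
    labels = [c for c, _ in _CLASS_MIX]
    probs = np.array([p for _, p in _CLASS_MIX])
    return list(rng.choice(labels, size=n, p=probs / probs.sum()))


def _background_variants(
    config: FamilySimConfig, rng: np.random.Generator
) -> tuple[list[VariantRecord], np.ndarray, np.ndarray]:
    """Background variant records plus their true AFs and database flags."""
    n = config.n_background
    bins = config.background_af_spectrum
    weights = np.array([b.weight for b in bins])
    bin_idx = rng.choice(len(bins), size=n, p=weights / weights.sum())
    afs = np.array([bins[i].af for i in bin_idx])
    in_db = np.array([bins[i].in_databases for i in bin_idx])
    classes = _draw_classes(rng, n)
    ref_alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    records = []
    for i in range(n):
        chrom = str((i % 22) + 1)
        pos = 1_000_000 + 977 * i  # deterministic, collision-free layout
        ref, alt = ref_alt[i % 4]
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                var_id=f"bg{i:05d}",
                gene=f"BG{i // 10:04d}",
                functional_class=classes[i],
            )
        )
    return records, afs, in_db


def _plant_carriers(config: FamilySimConfig, rng: np.random.Generator) -> dict[str, int]:
    """Assign planted-variant dosage per pedigree member.

    Affected members carry one copy with probability ``penetrance_affected``;
    unaffected members are non-carriers with probability
    ``penetrance_unaffected``; unknown-status members never carry.  Under
    complete penetrance the realized configuration is checked for obligate-
    carrier consistency: a carrier whose parents are both present in the
    pedigree and both non-carriers is impossible under Mendelian
    transmission of a fully penetrant dominant allele.
    """
    dosage: dict[str, int] = {}
    for member in config.pedigree:
        if member.affection == "affected":
            carrier = rng.random() < config.penetrance_affected
        elif member.affection == "unaffected":
            carrier = rng.random() >= config.penetrance_unaffected
        else:
            carrier = False
        dosage[member.individual_id] = 1 if carrier else 0
    complete = (
        config.penetrance_affected == 1.0 and config.penetrance_unaffected == 1.0
    )
    if complete:
        for member in config.pedigree:
            if dosage[member.individual_id] == 0:
                continue
            f, m = member.father_id, member.mother_id
            if f is not None and m is not None:
                if dosage.get(f, 0) == 0 and dosage.get(m, 0) == 0:
                    raise ValueError(
                        "obligate-carrier conflict: affected member "
                        f"{member.individual_id} must carry the planted allele "
                        f"but both parents ({f}, {m}) are non-carriers under "
                        "complete penetrance; the pedigree cannot segregate a "
                        "fully penetrant dominant allele with this affection "
                        "pattern"
                    )
    return dosage


def simulate_family(config: FamilySimConfig | None = None) -> FamilySimResult:
    """Simulate exome-like genotypes through a pedigree.

    Founders draw each background genotype from Hardy–Weinberg equilibrium
    at the variant's true AF; non-founders receive one allele per parent
    with probability 1/2 each (Mendelian transmission).  The planted variant
    is assigned by the penetrance model.  Deterministic given
    ``config.seed``.
    """
    config = config or FamilySimConfig()
    rng = _rng(config.seed, _STREAM_FAMILY)
    ped = config.pedigree
    order = ped.topological_order()
    bg_records, bg_afs, bg_in_db = _background_variants(config, rng)
    n_bg = len(bg_records)

    # Per-member background dosages, parents before children.
    member_dosage: dict[str, np.ndarray] = {}
    for iid in order:
        member = ped.member(iid)
        if member.father_id is None and member.mother_id is None:
            member_dosage[iid] = rng.binomial(2, bg_afs).astype(np.int8)
        else:
            pat = transmit_alleles(member_dosage[member.father_id], rng)
            mat = transmit_alleles(member_dosage[member.mother_id], rng)
            member_dosage[iid] = (pat + mat).astype(np.int8)

    planted = _plant_carriers(config, rng)
    planted_rec = replace(config.planted_variant)

    variants = [planted_rec] + bg_records
    keys = [v.key for v in variants]
    samples = [s for s in config.genotyped_ids if s in ped]
    dosages = np.empty((len(samples), len(variants)), dtype=np.int8)
    for i, s in enumerate(samples):
        dosages[i, 0] = planted[s]
        dosages[i, 1:] = member_dosage[s]
    genotypes = GenotypeMatrix(samples, keys, dosages)

    # Emulated database AF tables: variants flagged in_databases are
    # reported at their true AF; database-novel variants and the planted
    # variant are absent.
    af_sources: dict[str, dict[str, float]] = {s: {} for s in DEFAULT_AF_SOURCES}
    for rec, af, in_db in zip(bg_records, bg_afs, bg_in_db):
        if in_db:
            for s in DEFAULT_AF_SOURCES:
                af_sources[s][rec.key] = float(af)
                rec.af_by_source[s] = float(af)

    truth = pd.DataFrame(
        {
            "variant_key": keys,
            "role": ["planted"] + ["background"] * n_bg,
            "true_af": [0.0] + list(bg_afs),
            "in_databases": [False] + list(bg_in_db),
            "gene": [v.gene for v in variants],
            "functional_class": [v.functional_class for v in variants],
        }
    )
    return FamilySimResult(variants, genotypes, ped, truth, af_sources)


# ---------------------------------------------------------------------------
# Case-control cohort


@dataclass(frozen=True)
class GeneModel:
    """Rare-variant content of one gene in the cohort simulator.

    ``mafs`` are true population minor allele frequencies of the gene's rare
    variants; ``odds_ratio`` multiplies the per-variant carrier odds in
    cases (1.0 = null gene).
    """

    name: str
    mafs: tuple[float, ...]
    odds_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.mafs:
            raise ValueError(f"gene {self.name}: at least one variant required")
        for maf in self.mafs:
            if not 0.0 < maf <= 0.5:
                raise ValueError(
                    f"gene {self.name}: MAF must lie in (0, 0.5], got {maf}"
                )
        if self.odds_ratio <= 0:
            raise ValueError(f"gene {self.name}: odds ratio must be > 0")


def default_gene_models(target_or: float = 1.0) -> list[GeneModel]:
    """Five-gene cohort model: one chromatin-remodeller target gene plus
    four histone-modifying comparator genes.

    Variant counts and aggregate control carrier frequencies emulate a
    targeted-sequencing screen (target gene: 23 rare variants, ~3% control
    carrier frequency).  ``target_or`` sets the target gene's carrier odds
    ratio; comparators are null.
    """
    return [
        GeneModel("EP400", (0.0007,) * 23, odds_ratio=target_or),
        GeneModel("HDAC4", (0.00115,) * 8, odds_ratio=1.0),
        GeneModel("KMT2D", (0.00215,) * 20, odds_ratio=1.0),
        GeneModel("KDM6A", (0.00112,) * 7, odds_ratio=1.0),
        GeneModel("NSD1", (0.00135,) * 15, odds_ratio=1.0),
    ]


@dataclass
class CohortSimConfig:
    n_cases: int = 285
    n_controls: int = 445
    genes: list[GeneModel] = field(default_factory=default_gene_models)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not self.genes:
            raise ValueError("at least one gene model required")


@dataclass
class CohortSimResult:
    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    design: CohortDesign
    truth: pd.DataFrame  # variant_key, gene, true_maf, odds_ratio
    af_sources: dict[str, dict[str, float]]


def _cohort_variants(config: CohortSimConfig) -> tuple[list[VariantRecord], np.ndarray, np.ndarray]:
    records: list[VariantRecord] = []
    mafs: list[float] = []
    ors: list[float] = []
    pos = 5_000_000
    for g_idx, gene in enumerate(config.genes):
        chrom = str((g_idx % 22) + 1)
        for v_idx, maf in enumerate(gene.mafs):
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref="C",
                    alt="T",
                    var_id=f"{gene.name}_v{v_idx:03d}",
                    gene=gene.name,
                    functional_class="nonsynonymous",
                )
            )
            mafs.append(maf)
            ors.append(gene.odds_ratio)
            pos += 1009
    return records, np.array(mafs), np.array(ors)


def simulate_case_control(config: CohortSimConfig | None = None) -> CohortSimResult:
    """Simulate a case-control cohort with per-gene carrier enrichment.

    Controls draw genotypes from HWE at each variant's MAF.  Cases are
    carriers with probability obtained by multiplying the HWE carrier odds
    by the gene's odds ratio; carrier genotype (het vs hom-alt) keeps the
    HWE-conditional proportions.  Deterministic given ``config.seed``.
    """
    config = config or CohortSimConfig()
    rng = _rng(config.seed, _STREAM_COHORT)
    records, mafs, ors = _cohort_variants(config)
    m = len(records)

    p_het = 2 * mafs * (1 - mafs)
    p_hom = mafs**2
    p_carrier = p_het + p_hom
    odds = p_carrier / (1 - p_carrier)
    p_carrier_case = odds * ors / (1 + odds * ors)
    hom_given_carrier = p_hom / p_carrier

    case_ids = [f"case{i:04d}" for i in range(config.n_cases)]
    control_ids = [f"ctrl{i:04d}" for i in range(config.n_controls)]

    def draw(n: int, p_carr: np.ndarray) -> np.ndarray:
        carrier = rng.random((n, m)) < p_carr
        hom = rng.random((n, m)) < hom_given_carrier
        return np.where(carrier, np.where(hom, 2, 1), 0).astype(np.int8)

    case_dos = draw(config.n_cases, p_carrier_case)
    ctrl_dos = draw(config.n_controls, p_carrier)
    dosages = np.vstack([case_dos, ctrl_dos])
    keys = [r.key for r in records]
    genotypes = GenotypeMatrix(case_ids + control_ids, keys, dosages)
    design = CohortDesign(case_ids, control_ids)

    af_sources: dict[str, dict[str, float]] = {s: {} for s in DEFAULT_AF_SOURCES}
    for rec, maf in zip(records, mafs):
        for s in DEFAULT_AF_SOURCES:
            af_sources[s][rec.key] = float(maf)
            rec.af_by_source[s] = float(maf)

    truth = pd.DataFrame(
        {
            "variant_key": keys,
            "gene": [r.gene for r in records],
            "true_maf": mafs,
            "odds_ratio": ors,
        }
    )
    return CohortSimResult(records, genotypes, design, truth, af_sources)


def simulate_null_cohort(
    n_cases: int,
    n_controls: int,
    gene_model: GeneModel | Sequence[GeneModel],
    n_replicates: int,
    seed: int = 0,
) -> Iterator[CohortSimResult]:
    """Yield replicate cohorts simulated under the null (odds ratio 1).

    Each replicate uses a seed derived from ``seed`` and the replicate
    index, so individual replicates are reproducible in isolation.
    """
    genes = [gene_model] if isinstance(gene_model, GeneModel) else list(gene_model)
    null_genes = [replace(g, odds_ratio=1.0) for g in genes]
    for rep in range(n_replicates):
        cfg = CohortSimConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            genes=null_genes,
            seed=(seed * 100_003 + rep) % (2**31),
        )
        yield simulate_case_control(cfg)


def simulate_control_panel(
    variants: Sequence[VariantRecord],
    true_afs: Sequence[float],
    n_controls: int = 445,
    seed: int = 0,
    force_carrier: Sequence[str] = (),
) -> GenotypeMatrix:
    """HWE genotypes for a control screening panel at given variants.

    ``force_carrier`` lists variant keys planted as heterozygous in one
    control (used to exercise the control-exclusion stage the way a
    candidate found in healthy controls would be).
    """
    rng = _rng(seed, _STREAM_CONTROL_PANEL)
    afs = np.asarray(true_afs, dtype=float)
    if len(afs) != len(variants):
        raise ValueError("true_afs length must match variants")
    dosages = rng.binomial(2, afs, size=(n_controls, len(afs))).astype(np.int8)
    keys = [v.key for v in variants]
    for key in force_carrier:
        j = keys.index(key)
        dosages[:, j] = 0
        dosages[0, j] = 1
    samples = [f"panel{i:04d}" for i in range(n_controls)]
    return GenotypeMatrix(samples, keys, dosages)


# ---------------------------------------------------------------------------
# File output


def _write_af_tables(prefix: str, af_sources: dict[str, dict[str, float]]) -> list[str]:
    paths = []
    for source, table in af_sources.items():
        path = f"{prefix}.af.{source}.tsv"
        rows = []
        for key, af in table.items():
            chrom, pos, ref, alt = key.split(":")
            rows.append((chrom, pos, ref, alt, af))
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
            path, sep="\t", index=False
        )
        paths.append(path)
    return paths


def _write_annotation(prefix: str, variants: Sequence[VariantRecord]) -> str:
    path = f"{prefix}.anno.tsv"
    rows = [
        (v.chrom, v.pos, v.ref, v.alt, v.gene, v.functional_class) for v in variants
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "functional_class"]
    ).to_csv(path, sep="\t", index=False)
    return path


def write_family_dataset(result: FamilySimResult, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write VCF, PED, annotation, AF tables and the truth table.

    Returns a map of logical name -> path.
    """
    prefix = str(out_prefix)
    paths = {
        "vcf": f"{prefix}.vcf",
        "ped": f"{prefix}.ped",
        "truth": f"{prefix}.truth.tsv",
    }
    write_vcf(paths["vcf"], result.variants, result.genotypes)
    write_ped(paths["ped"], result.pedigree)
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["anno"] = _write_annotation(prefix, result.variants)
    for p in _write_af_tables(prefix, result.af_sources):
        source = p.split(".af.")[1].removesuffix(".tsv")
        paths[f"af:{source}"] = p
    return paths


def write_cohort_dataset(result: CohortSimResult, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write VCF, sample-label table, annotation, AF tables and truth table."""
    prefix = str(out_prefix)
    paths = {
        "vcf": f"{prefix}.vcf",
        "labels": f"{prefix}.labels.tsv",
        "truth": f"{prefix}.truth.tsv",
    }
    write_vcf(paths["vcf"], result.variants, result.genotypes)
    labels = pd.DataFrame(
        {
            "sample_id": result.design.case_ids + result.design.control_ids,
            "status": ["case"] * result.design.n_cases
            + ["control"] * result.design.n_controls,
        }
    )
    labels.to_csv(paths["labels"], sep="\t", index=False)
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["anno"] = _write_annotation(prefix, result.variants)
    for p in _write_af_tables(prefix, result.af_sources):
        source = p.split(".af.")[1].removesuffix(".tsv")
        paths[f"af:{source}"] = p
    return paths
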