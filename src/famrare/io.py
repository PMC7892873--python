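"""Data model and readers/writers for VCF, PED and tabular annotation inputs.

The pipeline works on four small containers:

* :class:`VariantRecord` — one alternate allele at a genomic position,
  together with its gene, functional class and per-database allele
  frequencies.
* :class:`GenotypeMatrix` — a samples × variants allele-dosage matrix
  (0/1/2, with missing genotypes) and optional per-genotype qualities.
* :class:`Pedigree` — family structure with affection status.
* :class:`CohortDesign` — disjoint case and control sample-id sets.

Variant identity throughout the package is the string ``chrom:pos:ref:alt``
with 1-based VCF coordinates.  Inputs are assumed pre-normalized: no
left-alignment or trimming is attempted, so two representations of the same
indel are distinct keys.  Multi-allelic VCF sites are split into one record
per alternate allele on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "Pedigree",
    "PedigreeMember",
    "CohortDesign",
    "FormatError",
    "FUNCTIONAL_CLASSES",
    "normalize_functional_class",
    "variant_key",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_frequency_table",
    "read_annotation_table",
    "merge_frequency_sources",
]

MISSING_DOSAGE = -1

#: Canonical functional classes used by the deleteriousness filter.
FUNCTIONAL_CLASSES = (
    "stop-gain",
    "stop-loss",
    "nonsynonymous",
    "splice-site",
    "synonymous",
    "other",
)

#: Deleterious functional classes: protein-truncating or protein-altering.
DELETERIOUS_CLASSES = frozenset(
    {"stop-gain", "stop-loss", "nonsynonymous", "splice-site"}
)

# Annotation tools emit several spellings for the same class (ANNOVAR-style
# "stopgain", "nonsynonymous SNV", "splicing", ...).  The alias table is
# explicit; anything unrecognized maps to "other".
_CLASS_ALIASES = {
    "stop-gain": "stop-gain",
    "stopgain": "stop-gain",
    "stop_gain": "stop-gain",
    "stopgain snv": "stop-gain",
    "nonsense": "stop-gain",
    "stop-loss": "stop-loss",
    "stoploss": "stop-loss",
    "stop_loss": "stop-loss",
    "stoploss snv": "stop-loss",
    "nonsynonymous": "nonsynonymous",
    "nonsynonymous snv": "nonsynonymous",
    "non-synonymous": "nonsynonymous",
    "missense": "nonsynonymous",
    "missense_variant": "nonsynonymous",
    "splice-site": "splice-site",
    "splicing": "splice-site",
    "splice_site": "splice-site",
    "splice": "splice-site",
    "synonymous": "synonymous",
    "synonymous snv": "synonymous",
    "silent": "synonymous",
}


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def normalize_functional_class(label: str) -> str:
    """Map a free-text functional class label to a canonical class.

    Unknown labels become ``"other"`` rather than erroring, since exome
    annotation tables routinely contain classes the cascade never filters on
    (UTR, intronic, intergenic, ...).
    """
    return _CLASS_ALIASES.get(label.strip().lower(), "other")


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class VariantRecord:
    """A single alternate allele at a genomic position.

    ``af_by_source`` maps a named allele-frequency database (e.g. a
    population panel) to the variant's alternate allele frequency in that
    database; an absent key means the variant is not present in that source.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_id: str = ""
    gene: str = ""
    functional_class: str = "other"
    af_by_source: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("VariantRecord holds exactly one alternate allele")
        for source, af in self.af_by_source.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"AF for source {source!r} outside [0,1]: {af}")

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def max_af(self, sources: Iterable[str] | None = None) -> float:
        """Maximum allele frequency over the given sources (all by default).

        A variant absent from every consulted source has max AF 0.0.
        """
        if sources is None:
            vals = self.af_by_source.values()
        else:
            vals = [self.af_by_source[s] for s in sources if s in self.af_by_source]
        return max(vals, default=0.0)

    def in_any_source(self, sources: Iterable[str] | None = None) -> bool:
        if sources is None:
            return bool(self.af_by_source)
        return any(s in self.af_by_source for s in sources)


class GenotypeMatrix:
    """Samples × variants allele-dosage matrix with per-genotype quality.

    Dosages are stored as int8 with ``-1`` for a missing genotype; qualities
    as float with NaN for missing.  ``genotype_quality`` may be None when the
    source VCF carried no GQ field.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_keys: Sequence[str],
        dosages: np.ndarray,
        genotype_quality: np.ndarray | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variant_keys = list(variant_keys)
        self.dosages = np.asarray(dosages, dtype=np.int8)
        expected = (len(self.sample_ids), len(self.variant_keys))
        if self.dosages.shape != expected:
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} != {expected}"
            )
        if genotype_quality is not None:
            genotype_quality = np.asarray(genotype_quality, dtype=float)
            if genotype_quality.shape != expected:
                raise ValueError(
                    f"genotype_quality shape {genotype_quality.shape} != {expected}"
                )
        self.genotype_quality = genotype_quality
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._variant_index = {v: j for j, v in enumerate(self.variant_keys)}
        if len(self._sample_index) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self._variant_index) != len(self.variant_keys):
            raise ValueError("duplicate variant keys")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def variant_index(self, key: str) -> int:
        return self._variant_index[key]

    def has_variant(self, key: str) -> bool:
        return key in self._variant_index

    def dosage_vector(self, key: str) -> np.ndarray:
        """Dosages for one variant across samples (int8, -1 = missing)."""
        return self.dosages[:, self._variant_index[key]]

    def call_rate(self, key: str) -> float:
        """Fraction of non-missing genotypes at a variant."""
        col = self.dosage_vector(key)
        return float(np.mean(col != MISSING_DOSAGE))

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        gq = None if self.genotype_quality is None else self.genotype_quality[idx]
        return GenotypeMatrix(sample_ids, self.variant_keys, self.dosages[idx], gq)

    def subset_variants(self, keys: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._variant_index[k] for k in keys]
        gq = (
            None
            if self.genotype_quality is None
            else self.genotype_quality[:, idx]
        )
        return GenotypeMatrix(self.sample_ids, keys, self.dosages[:, idx], gq)

    def copy(self) -> "GenotypeMatrix":
        gq = None if self.genotype_quality is None else self.genotype_quality.copy()
        return GenotypeMatrix(
            self.sample_ids, self.variant_keys, self.dosages.copy(), gq
        )


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    affection: str  # "affected" | "unaffected" | "unknown"


class Pedigree:
    """Family structure with affection status.

    Parent ids, when present, must refer either to listed members or to
    implicitly declared founders; cycles (an individual being its own
    ancestor) are rejected at construction.
    """

    def __init__(self, members: Sequence[PedigreeMember], family_id: str = "FAM1"):
        self.family_id = family_id
        self.members = list(members)
        self._by_id = {m.individual_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise ValueError("duplicate individual id in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if iid in state:
                if state[iid] == 0:
                    raise ValueError(
                        f"pedigree cycle: {' -> '.join(stack + [iid])}"
                    )
                return
            state[iid] = 0
            member = self._by_id.get(iid)
            if member is not None:
                for parent in (member.father_id, member.mother_id):
                    if parent is not None:
                        visit(parent, stack + [iid])
            state[iid] = 1

        for m in self.members:
            visit(m.individual_id, [])

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def member(self, individual_id: str) -> PedigreeMember:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    @property
    def affected_ids(self) -> list[str]:
        return [m.individual_id for m in self.members if m.affection == "affected"]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.individual_id for m in self.members if m.affection == "unaffected"]

    @property
    def founder_ids(self) -> list[str]:
        return [
            m.individual_id
            for m in self.members
            if m.father_id is None and m.mother_id is None
        ]

    def topological_order(self) -> list[str]:
        """Member ids ordered so every parent precedes its children."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(iid: str) -> None:
            if iid in seen or iid not in self._by_id:
                return
            seen.add(iid)
            m = self._by_id[iid]
            for parent in (m.father_id, m.mother_id):
                if parent is not None:
                    visit(parent)
            order.append(iid)

        for m in self.members:
            visit(m.individual_id)
        return order


@dataclass
class CohortDesign:
    """Disjoint case and control sample-id sets for association testing."""

    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"samples in both cases and controls: {sorted(overlap)}")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)

    def phenotype_vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 phenotype aligned to ``sample_ids`` (1 = case).

        Raises if a sample is in neither group.
        """
        cases, controls = set(self.case_ids), set(self.control_ids)
        y = np.empty(len(sample_ids), dtype=np.int64)
        for i, s in enumerate(sample_ids):
            if s in cases:
                y[i] = 1
            elif s in controls:
                y[i] = 0
            else:
                raise KeyError(f"sample {s!r} in neither cases nor controls")
        return y


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a VCF v4.x file into variant records and a genotype matrix.

    Multi-allelic sites are split into one :class:`VariantRecord` per
    alternate allele; the per-sample dosage for each record is the count of
    that specific alternate allele in the genotype.  ``./.`` genotypes are
    missing; absent GQ values are missing qualities.  Non-diploid genotypes
    are a format error.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    any_gq = False
    for rec_no, var in enumerate(vcf, start=1):
        genotypes = var.genotypes  # [[a0, a1, phased], ...]
        for g in genotypes:
            if len(g) != 3:  # alleles + phase flag
                raise FormatError(
                    f"non-diploid genotype at record {rec_no} "
                    f"({var.CHROM}:{var.POS})"
                )
        gq = var.gt_quals  # -1 where missing / absent
        has_gq = gq is not None and np.any(np.asarray(gq) >= 0)
        any_gq = any_gq or has_gq
        for alt_index, alt in enumerate(var.ALT):
            allele_code = alt_index + 1
            dos = np.empty(len(samples), dtype=np.int8)
            for i, g in enumerate(genotypes):
                a0, a1 = g[0], g[1]
                if a0 < 0 or a1 < 0:
                    dos[i] = MISSING_DOSAGE
                else:
                    dos[i] = int(a0 == allele_code) + int(a1 == allele_code)
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    var_id=var.ID or "",
                )
            )
            dosage_cols.append(dos)
            if has_gq:
                col = np.asarray(gq, dtype=float).copy()
                col[col < 0] = np.nan
            else:
                col = np.full(len(samples), np.nan)
            gq_cols.append(col)
    vcf.close()
    n_var = len(records)
    dosages = (
        np.column_stack(dosage_cols)
        if n_var
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    gq_matrix = None
    if any_gq and n_var:
        gq_matrix = np.column_stack(gq_cols)
    keys = [r.key for r in records]
    return records, GenotypeMatrix(samples, keys, dosages, gq_matrix)


def write_vcf(
    path: str | os.PathLike,
    records: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
) -> None:
    """Write records and genotypes as a minimal VCF v4.2 text file.

    Each record is written as its own biallelic line (the split
    representation used internally), ordered as given.  GQ is emitted only
    when the matrix carries qualities.
    """
    with_gq = genotypes.genotype_quality is not None
    fmt = "GT:GQ" if with_gq else "GT"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    seen_chroms: dict[str, None] = {}
    for rec in records:
        seen_chroms.setdefault(rec.chrom)
    lines.extend(f"##contig=<ID={chrom}>" for chrom in seen_chroms)
    if with_gq:
        lines.append(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">'
        )
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    lines.append("\t".join(header[:7] + ["INFO"] + header[7:] + genotypes.sample_ids))
    for rec in records:
        j = genotypes.variant_index(rec.key)
        fields = [
            rec.chrom,
            str(rec.pos),
            rec.var_id or ".",
            rec.ref,
            rec.alt,
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for i in range(genotypes.n_samples):
            d = genotypes.dosages[i, j]
            if d == MISSING_DOSAGE:
                gt = "./."
            else:
                gt = ["0/0", "0/1", "1/1"][d]
            if with_gq:
                q = genotypes.genotype_quality[i, j]
                gt += ":." if np.isnan(q) else f":{int(round(q))}"
            fields.append(gt)
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_PHENO_CODES = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}


def read_ped(path: str | os.PathLike) -> Pedigree:
    """Read a 6-column whitespace-delimited pre-makeped pedigree file.

    Columns: family, individual, father, mother, sex (1 = male, 2 = female,
    0 = unknown), phenotype (2 = affected, 1 = unaffected, 0/-9 = unknown).
    A ``0`` parent id means a founder on that side.
    """
    members: list[PedigreeMember] = []
    family_id = "FAM1"
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise FormatError(
                    f"{path} line {line_no}: expected 6 columns, got {len(cols)}"
                )
            fam, iid, father, mother, sex, pheno = cols
            family_id = fam
            if iid in seen:
                raise FormatError(f"{path} line {line_no}: duplicate individual {iid}")
            seen.add(iid)
            if sex not in _SEX_CODES:
                raise FormatError(f"{path} line {line_no}: unknown sex code {sex!r}")
            if pheno not in _PHENO_CODES:
                raise FormatError(
                    f"{path} line {line_no}: unknown phenotype code {pheno!r}"
                )
            members.append(
                PedigreeMember(
                    individual_id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES[sex],
                    affection=_PHENO_CODES[pheno],
                )
            )
    return Pedigree(members, family_id=family_id)


def write_ped(path: str | os.PathLike, pedigree: Pedigree) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for m in pedigree:
            fh.write(
                " ".join(
                    [
                        pedigree.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        sex_code[m.sex],
                        pheno_code[m.affection],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tabular inputs


def read_frequency_table(path: str | os.PathLike, source_name: str) -> dict[str, float]:
    """Read a TSV allele-frequency table for one named database.

    Required columns: chrom, pos, ref, alt, af.  Returns a map from
    ``chrom:pos:ref:alt`` to allele frequency; variants not listed are
    absent from the source.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    af = df["af"].to_numpy(dtype=float)
    bad = (af < 0) | (af > 1) | ~np.isfinite(af)
    if bad.any():
        row = df.index[bad][0]
        raise FormatError(
            f"{path}: af outside [0,1] at row {row} (source {source_name!r})"
        )
    return {
        variant_key(r.chrom, int(r.pos), r.ref, r.alt): float(r.af)
        for r in df.itertuples()
    }


def merge_frequency_sources(
    records: Sequence[VariantRecord], sources: Mapping[str, Mapping[str, float]]
) -> None:
    """Attach per-source allele frequencies to records in place.

    ``sources`` maps source name -> (variant key -> AF).  Keys absent from a
    source leave that source out of the record's ``af_by_source``.
    """
    for rec in records:
        for name, table in sources.items():
            if rec.key in table:
                rec.af_by_source[name] = table[rec.key]


def read_annotation_table(path: str | os.PathLike) -> dict[str, tuple[str, str]]:
    """Read a TSV variant annotation table (gene + functional class).

    Required columns: chrom, pos, ref, alt, gene, functional_class.  Class
    labels are normalized through the alias table; unknown labels become
    "other".
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "gene": str}
    )
    required = {"chrom", "pos", "ref", "alt", "gene", "functional_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return {
        variant_key(r.chrom, int(r.pos), r.ref, r.alt): (
            r.gene,
            normalize_functional_class(str(r.functional_class)),
        )
        for r in df.itertuples()
    }


def apply_annotation(
    records: Sequence[VariantRecord], annotation: Mapping[str, tuple[str, str]]
) -> None:
    """Attach gene and functional class to records in place."""
    for rec in records:
        if rec.key in annotation:
            rec.gene, rec.functional_class = annotation[rec.key]
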