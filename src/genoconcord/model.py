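"""Core data model for genotype concordance evaluation.

Genotype calls are unordered diploid allele pairs over {A, C, G, T}, or
missing.  Internally every call is stored as a single signed-byte *pair
code* so that whole datasets live in numpy matrices and comparisons
vectorise:

* allele index: A=0, C=1, G=2, T=3 (so strand complement is ``3 - i``);
* an unordered pair (i, j) with i <= j gets code ``4*i + j``;
* missing calls get :data:`MISSING_CODE` (-1).

All code-level lookup tables (heterozygosity, strand flip) are built once
at import from this scheme.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Allele",
    "GenotypeCall",
    "MISSING",
    "MISSING_CODE",
    "VariantRecord",
    "SampleRecord",
    "GenotypeDataset",
    "DosageTable",
    "ProcessClass",
    "ComparisonOutcome",
    "DiscrepancyType",
    "ComparisonConfig",
    "encode_pair",
    "decode_code",
    "complement_code",
    "normalize_chromosome",
]


class Allele(str, enum.Enum):
    """One of the four canonical DNA bases."""

    A = "A"
    C = "C"
    G = "G"
    T = "T"

    @property
    def index(self) -> int:
        return _ALLELE_INDEX[self.value]

    @property
    def complement(self) -> "Allele":
        # A<->T, C<->G; an involution by construction (index -> 3 - index).
        return _ALLELES_BY_INDEX[3 - self.index]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_ALLELE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_ALLELES_BY_INDEX = [Allele.A, Allele.C, Allele.G, Allele.T]

MISSING_CODE: int = -1

#: number of distinct unordered-pair codes (0..15 used sparsely; i<=j only)
N_CODES: int = 16


def encode_pair(a: Allele, b: Allele) -> int:
    """Pair code of the unordered allele pair {a, b} (order-insensitive)."""
    i, j = sorted((a.index, b.index))
    return 4 * i + j


def decode_code(code: int) -> Optional[tuple[Allele, Allele]]:
    """Inverse of :func:`encode_pair`; ``None`` for the missing code."""
    if code == MISSING_CODE:
        return None
    i, j = divmod(int(code), 4)
    if not (0 <= i <= j <= 3):
        raise ValueError(f"invalid genotype pair code: {code}")
    return (_ALLELES_BY_INDEX[i], _ALLELES_BY_INDEX[j])


def _build_flip_table() -> np.ndarray:
    # maps a pair code to the code of the strand-complemented pair;
    # index 16 (alias of MISSING via mod) is unused -- flips are applied
    # only to non-missing entries.
    table = np.full(N_CODES, MISSING_CODE, dtype=np.int8)
    for i in range(4):
        for j in range(i, 4):
            ci, cj = sorted((3 - i, 3 - j))
            table[4 * i + j] = 4 * ci + cj
    return table


def _build_het_table() -> np.ndarray:
    table = np.zeros(N_CODES, dtype=bool)
    for i in range(4):
        for j in range(i, 4):
            table[4 * i + j] = i != j
    return table


#: FLIP_CODE[code] = code of the complemented pair (valid codes only)
FLIP_CODE: np.ndarray = _build_flip_table()
#: IS_HET[code] = True iff the pair is heterozygous (valid codes only)
IS_HET: np.ndarray = _build_het_table()


def complement_code(code: int) -> int:
    """Strand-complement a pair code; missing stays missing."""
    if code == MISSING_CODE:
        return MISSING_CODE
    return int(FLIP_CODE[code])


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid allele pair, or missing.

    Equality is order-insensitive ({A,C} == {C,A}); a call is either fully
    present or missing — half-calls are normalised away at parse time.
    """

    code: int = MISSING_CODE

    @classmethod
    def from_alleles(cls, a: Allele, b: Allele) -> "GenotypeCall":
        return cls(encode_pair(a, b))

    @classmethod
    def from_strings(cls, a: str, b: str) -> "GenotypeCall":
        return cls.from_alleles(Allele(a), Allele(b))

    @property
    def is_missing(self) -> bool:
        return self.code == MISSING_CODE

    @property
    def alleles(self) -> Optional[frozenset[Allele]]:
        pair = decode_code(self.code)
        return None if pair is None else frozenset(pair)

    @property
    def is_het(self) -> bool:
        if self.is_missing:
            raise ValueError("missing call has no zygosity")
        return bool(IS_HET[self.code])

    @property
    def is_hom(self) -> bool:
        return not self.is_het

    def complemented(self) -> "GenotypeCall":
        return GenotypeCall(complement_code(self.code))

    def __str__(self) -> str:
        pair = decode_code(self.code)
        if pair is None:
            return "NA"
        return pair[0].value + pair[1].value


MISSING = GenotypeCall(MISSING_CODE)


def normalize_chromosome(label: str) -> str:
    """Normalise a chromosome label for cross-dataset comparison.

    Strips any leading ``chr`` prefix (case-insensitive) so that ``chr1``
    and ``1`` compare equal.
    """
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: the harmonization key plus its two alleles."""

    chromosome: str
    position: int
    rsid: Optional[str]
    allele_a: Allele
    allele_b: Allele

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(
                f"monomorphic variant record at {self.chromosome}:{self.position}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def chrom_norm(self) -> str:
        return normalize_chromosome(self.chromosome)

    @property
    def allele_set(self) -> frozenset[Allele]:
        return frozenset((self.allele_a, self.allele_b))

    def complemented(self) -> "VariantRecord":
        return replace(
            self,
            allele_a=self.allele_a.complement,
            allele_b=self.allele_b.complement,
        )


@dataclass(frozen=True)
class SampleRecord:
    """Pedigree metadata for one individual."""

    sample_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sequenced: bool = False

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise ValueError(
                f"sample {self.sample_id}: exactly one parent present; "
                "individuals must have both parents or neither"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


def validate_pedigree(samples: Sequence[SampleRecord]) -> None:
    """Check parent references: present, and in the same family."""
    by_id = {s.sample_id: s for s in samples}
    if len(by_id) != len(samples):
        dupes = [s for s in {x.sample_id for x in samples}
                 if sum(x.sample_id == s for x in samples) > 1]
        raise ValueError(f"duplicate sample IDs in pedigree: {dupes}")
    for s in samples:
        for parent_id in (s.father_id, s.mother_id):
            if parent_id is None:
                continue
            parent = by_id.get(parent_id)
            if parent is None:
                raise ValueError(
                    f"sample {s.sample_id}: parent {parent_id} not in pedigree"
                )
            if parent.family_id != s.family_id:
                raise ValueError(
                    f"sample {s.sample_id} (family {s.family_id}): parent "
                    f"{parent_id} belongs to family {parent.family_id}"
                )


@dataclass
class GenotypeDataset:
    """A cohort of genotype calls: variants x samples matrix of pair codes.

    ``calls[v, s]`` is the pair code of sample ``samples[s]`` at variant
    ``variants[v]`` (``MISSING_CODE`` for missing).  Variant rsIDs need not
    be unique at this stage; uniqueness is enforced during harmonization.
    """

    variants: list[VariantRecord]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample ID: {sample_id}") from None

    def call(self, variant_index: int, sample_id: str) -> GenotypeCall:
        return GenotypeCall(int(self.calls[variant_index, self.sample_index(sample_id)]))

    def variant_key_index(self) -> dict[tuple[str, str], list[int]]:
        """Map (rsid, normalized chromosome) -> variant row indices."""
        index: dict[tuple[str, str], list[int]] = {}
        for i, v in enumerate(self.variants):
            if v.rsid is None:
                continue
            index.setdefault((v.rsid, v.chrom_norm), []).append(i)
        return index

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeDataset":
        cols = [self.sample_index(s) for s in keep]
        return GenotypeDataset(
            variants=list(self.variants),
            samples=list(keep),
            calls=self.calls[:, cols].copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class DosageTable:
    """Per-variant, per-sample expected minor-allele counts in [0, 2].

    ``values[v, s]`` is the dosage (NaN where absent), aligned to
    ``variant_keys`` and ``samples``.
    """

    variant_keys: list[tuple[str, str]]  # (rsid, chromosome)
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.variant_keys), len(self.samples)):
            raise ValueError("dosage matrix shape mismatch")
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < 0 or present.max() > 2):
            raise ValueError("dosage values must lie in [0, 2]")

    def equals(self, other: "DosageTable") -> bool:
        return (
            self.variant_keys == other.variant_keys
            and self.samples == other.samples
            and np.allclose(self.values, other.values, equal_nan=True)
        )


class ProcessClass(enum.IntEnum):
    """How a completed (GENO) genotype call was produced.

    ``SEQUENCED``/``IMPUTED`` apply only to sequenced individuals (the call
    is a raw sequence read, or fills a gap in the reads); ``INFERRED_*``
    apply only to unsequenced individuals, split by whether their family
    contains any sequenced member.
    """

    SEQUENCED = 0
    IMPUTED = 1
    INFERRED_FAM_SEQ = 2
    INFERRED_FAM_NOSEQ = 3


class ComparisonOutcome(enum.IntEnum):
    NOT_COMPARED = 0
    CONCORDANT = 1
    DISCREPANT = 2


class DiscrepancyType(enum.IntEnum):
    """Zygosity pattern of a discrepant GWAS-vs-GENO cell.

    ``HOM_TO_HET`` = homozygote on the chip, heterozygote in the completed
    calls (the pattern dominating imputation errors).  ``OTHER`` cannot
    occur for biallelic SNPs and is asserted against.
    """

    HOM_TO_HET = 0
    HET_TO_HOM = 1
    HOM_TO_OPP_HOM = 2
    OTHER = 3


@dataclass(frozen=True)
class ComparisonConfig:
    """Tunables of the comparison pipeline.

    call_rate_threshold
        Per-SNP minimum call rate (inclusive) in *both* datasets for the
        high-call-rate subset; default 0.98.
    outlier_gap_factor, outlier_min_count
        An individual is flagged as an outlier while their discrepancy
        count exceeds ``outlier_gap_factor`` times the next-highest count
        and is at least ``outlier_min_count``.
    dosage_integrality_tolerance
        Maximum |dosage - nearest of {0,1,2}| still considered integral.
    """

    call_rate_threshold: float = 0.98
    outlier_gap_factor: float = 3.0
    outlier_min_count: int = 5000
    dosage_integrality_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate_threshold <= 1.0:
            raise ValueError("call_rate_threshold must be in [0, 1]")
        if self.outlier_gap_factor <= 1.0:
            raise ValueError("outlier_gap_factor must be > 1")
        if self.outlier_min_count < 0:
            raise ValueError("outlier_min_count must be >= 0")
        if self.dosage_integrality_tolerance < 0:
            raise ValueError("dosage_integrality_tolerance must be >= 0")
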