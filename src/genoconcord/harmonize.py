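"""Strand harmonization and comparison-SNP selection between two datasets.

Two genotype datasets (typically GWAS chip on the left, sequence-derived
on the right) are matched on rsID + normalized chromosome.  A matched
variant pair is usable when the two allele pairs are identical (SAME) or
are each other's strand complements (FLIPPED, e.g. A/C vs T/G).  A/T and
C/G polymorphisms are strand-ambiguous — their two strand representations
are indistinguishable — and are discarded unconditionally, even when the
letters agree.  rsIDs must occur exactly once in EACH dataset; duplicated
rsIDs are dropped entirely.

Positions are carried but never used as a matching key: genome-build
drift between a chip manifest and a sequencing reference makes position
disagreement expected, so it is counted, not fatal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .model import (
    FLIP_CODE,
    MISSING_CODE,
    Allele,
    GenotypeDataset,
    VariantRecord,
)

__all__ = [
    "AlleleMatchStatus",
    "HarmonizedPair",
    "HarmonizationCounters",
    "HarmonizationResult",
    "complement_allele",
    "match_alleles",
    "select_comparison_snps",
    "orient_genotypes",
    "remap_pairs",
]

_AMBIGUOUS_PAIRS = (
    frozenset((Allele.A, Allele.T)),
    frozenset((Allele.C, Allele.G)),
)


class AlleleMatchStatus(enum.Enum):
    SAME = "same"
    FLIPPED = "flipped"
    AMBIGUOUS = "ambiguous"
    INCOMPATIBLE = "incompatible"


def complement_allele(a: Allele) -> Allele:
    """Watson-Crick complement (A<->T, C<->G); an involution."""
    return a.complement


def match_alleles(
    left: frozenset[Allele] | set[Allele] | tuple[Allele, Allele],
    right: frozenset[Allele] | set[Allele] | tuple[Allele, Allele],
) -> AlleleMatchStatus:
    """Classify how two biallelic allele pairs relate across strands.

    AMBIGUOUS takes precedence: an A/T or C/G pair on either side makes
    the variant unalignable regardless of letter agreement.  Otherwise
    SAME for equal sets, FLIPPED when one set is the complement of the
    other, INCOMPATIBLE for anything else.  Symmetric in its arguments.
    """
    lset, rset = frozenset(left), frozenset(right)
    if len(lset) != 2 or len(rset) != 2:
        raise ValueError("match_alleles requires two biallelic pairs")
    if lset in _AMBIGUOUS_PAIRS or rset in _AMBIGUOUS_PAIRS:
        return AlleleMatchStatus.AMBIGUOUS
    if lset == rset:
        return AlleleMatchStatus.SAME
    if lset == frozenset(a.complement for a in rset):
        return AlleleMatchStatus.FLIPPED
    return AlleleMatchStatus.INCOMPATIBLE


@dataclass(frozen=True)
class HarmonizedPair:
    """One variant retained for comparison, linked into both datasets."""

    variant_key: tuple[str, str]  # (rsid, normalized chromosome)
    left_index: int
    right_index: int
    flipped: bool  # right dataset's genotypes must be complemented


@dataclass
class HarmonizationCounters:
    """Per-reason exclusion tallies for the comparison-SNP selection.

    ``candidates`` counts rsIDs present in both datasets; the telescoping
    identity ``duplicate + chromosome_mismatch + ambiguous + incompatible
    + retained == candidates`` holds on every run.  ``missing_rsid_*``
    count variants excluded up front for lacking an rsID;
    ``position_mismatch`` counts retained pairs whose positions disagree
    (logged only, never an exclusion).
    """

    candidates: int = 0
    duplicate: int = 0
    chromosome_mismatch: int = 0
    ambiguous: int = 0
    incompatible: int = 0
    retained: int = 0
    missing_rsid_left: int = 0
    missing_rsid_right: int = 0
    position_mismatch: int = 0

    def check_telescoping(self) -> None:
        total = (
            self.duplicate
            + self.chromosome_mismatch
            + self.ambiguous
            + self.incompatible
            + self.retained
        )
        if total != self.candidates:
            raise AssertionError(
                f"harmonization counters do not partition candidates: "
                f"{total} != {self.candidates}"
            )


@dataclass
class HarmonizationResult:
    pairs: list[HarmonizedPair]
    counters: HarmonizationCounters

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _rsid_occurrences(dataset: GenotypeDataset) -> tuple[dict[str, list[int]], int]:
    occ: dict[str, list[int]] = {}
    missing = 0
    for i, v in enumerate(dataset.variants):
        if v.rsid is None:
            missing += 1
        else:
            occ.setdefault(v.rsid, []).append(i)
    return occ, missing


def select_comparison_snps(
    left: GenotypeDataset, right: GenotypeDataset
) -> HarmonizationResult:
    """Select the comparable SNP set between two datasets.

    Retains exactly the rsIDs occurring once in each dataset, on the same
    normalized chromosome, with non-ambiguous strand-alignable alleles.
    Pairs are returned in left-dataset order with ``flipped`` set where
    the right dataset must be complemented onto the left strand.
    """
    counters = HarmonizationCounters()
    left_occ, counters.missing_rsid_left = _rsid_occurrences(left)
    right_occ, counters.missing_rsid_right = _rsid_occurrences(right)

    pairs: list[HarmonizedPair] = []
    shared = set(left_occ) & set(right_occ)
    counters.candidates = len(shared)
    for rsid in shared:
        l_idx_list, r_idx_list = left_occ[rsid], right_occ[rsid]
        if len(l_idx_list) > 1 or len(r_idx_list) > 1:
            counters.duplicate += 1
            continue
        l_idx, r_idx = l_idx_list[0], r_idx_list[0]
        lv, rv = left.variants[l_idx], right.variants[r_idx]
        if lv.chrom_norm != rv.chrom_norm:
            counters.chromosome_mismatch += 1
            continue
        status = match_alleles(lv.allele_set, rv.allele_set)
        if status is AlleleMatchStatus.AMBIGUOUS:
            counters.ambiguous += 1
            continue
        if status is AlleleMatchStatus.INCOMPATIBLE:
            counters.incompatible += 1
            continue
        if lv.position != rv.position:
            counters.position_mismatch += 1
        counters.retained += 1
        pairs.append(
            HarmonizedPair(
                variant_key=(rsid, lv.chrom_norm),
                left_index=l_idx,
                right_index=r_idx,
                flipped=status is AlleleMatchStatus.FLIPPED,
            )
        )
    pairs.sort(key=lambda p: p.left_index)
    counters.check_telescoping()
    return HarmonizationResult(pairs=pairs, counters=counters)


def orient_genotypes(
    dataset: GenotypeDataset, pairs: Sequence[HarmonizedPair]
) -> GenotypeDataset:
    """Complement the right dataset's flipped variants onto the left strand.

    Both the calls and the variant's allele pair are complemented, so
    applying the same orientation twice restores the original dataset.
    MISSING calls are unchanged.
    """
    variants = list(dataset.variants)
    calls = dataset.calls.copy()
    for pair in pairs:
        idx = pair.right_index
        if not 0 <= idx < dataset.n_variants:
            raise ValidationError(
                f"harmonized pair {pair.variant_key} points outside the "
                f"dataset (index {idx} of {dataset.n_variants})"
            )
        if not pair.flipped:
            continue
        variants[idx] = variants[idx].complemented()
        row = calls[idx]
        present = row != MISSING_CODE
        row[present] = FLIP_CODE[row[present]]
    return GenotypeDataset(
        variants=variants, samples=list(dataset.samples), calls=calls
    )


def remap_pairs(
    pairs: Sequence[HarmonizedPair], dataset: GenotypeDataset
) -> list[HarmonizedPair]:
    """Re-target harmonized pairs' right side at another dataset.

    Used to carry one harmonization over to a sibling dataset sharing the
    same variant universe and strand (e.g. the raw sequence VCF alongside
    the completed calls).  Pairs whose key is absent or duplicated in the
    target are dropped.
    """
    index = dataset.variant_key_index()
    out: list[HarmonizedPair] = []
    for p in pairs:
        hits = index.get(p.variant_key, [])
        if len(hits) != 1:
            continue
        out.append(
            HarmonizedPair(
                variant_key=p.variant_key,
                left_index=p.left_index,
                right_index=hits[0],
                flipped=p.flipped,
            )
        )
    return out
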