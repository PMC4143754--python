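"""Discrepancy evaluation engine.

Compares GWAS-chip calls against the completed ("GENO") calls over the
harmonized SNP set, labels every cell with the process that produced its
completed call, and accumulates stratified statistics:

* by process — sequenced (the GENO call is a raw sequence read), imputed
  (a sequenced individual's gap filled in), or inferred (an unsequenced
  individual, split by whether the family has any sequenced member);
* by individual — discrepancy counts, feeding sample-swap outlier
  detection;
* by family — (N, D, D/N) per sequenced / nonsequenced / all strata;
* by variant — discrepancy counts and the zero-discrepancy fraction.

A discrepancy is a cell called (non-missing) in BOTH datasets whose
unordered allele pairs differ; a missing call on either side is never a
discrepancy.  The process label of a sequenced individual's cell comes
from the raw sequence VCF: present there means the completed call is a
read, absent means it was imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .harmonize import HarmonizedPair, remap_pairs
from .model import (
    IS_HET,
    MISSING_CODE,
    ComparisonConfig,
    ComparisonOutcome,
    DiscrepancyType,
    DosageTable,
    GenotypeCall,
    GenotypeDataset,
    ProcessClass,
    SampleRecord,
)

__all__ = [
    "ProcessSummary",
    "FamilySummary",
    "AccumulationResult",
    "DosageAuditReport",
    "classify_process",
    "compare_call",
    "classify_discrepancy",
    "call_rate",
    "select_high_call_rate",
    "accumulate",
    "zero_discrepancy_fraction",
    "detect_outliers",
    "remove_samples",
    "dosage_audit",
    "families_with_sequenced",
]


# ---------------------------------------------------------------------------
# Summary row types


@dataclass(frozen=True)
class ProcessSummary:
    """One row of the by-process table: subjects, call count, discrepancy rate."""

    process: str
    subjects: int
    genotypes: int
    discrepant: int

    @property
    def percent_discrepant(self) -> float:
        if self.genotypes == 0:
            return 0.0
        return 100.0 * self.discrepant / self.genotypes

    def __post_init__(self) -> None:
        if not 0 <= self.discrepant <= self.genotypes:
            raise ValueError("discrepant count must lie in [0, genotypes]")


@dataclass(frozen=True)
class FamilySummary:
    """One family's (N, D) per stratum; D/N is discrepancies per individual."""

    family_id: str
    n_seq: int
    d_seq: int
    n_nonseq: int
    d_nonseq: int

    @property
    def n_all(self) -> int:
        return self.n_seq + self.n_nonseq

    @property
    def d_all(self) -> int:
        return self.d_seq + self.d_nonseq

    @staticmethod
    def _ratio(d: int, n: int) -> Optional[float]:
        return d / n if n > 0 else None

    @property
    def d_over_n_seq(self) -> Optional[float]:
        return self._ratio(self.d_seq, self.n_seq)

    @property
    def d_over_n_nonseq(self) -> Optional[float]:
        return self._ratio(self.d_nonseq, self.n_nonseq)

    @property
    def d_over_n_all(self) -> Optional[float]:
        return self._ratio(self.d_all, self.n_all)


# ---------------------------------------------------------------------------
# Scalar operations


def classify_process(
    sample: SampleRecord,
    vcf_call: GenotypeCall,
    family_has_sequenced: bool,
) -> ProcessClass:
    """Label how a completed call for *sample* was produced.

    For a sequenced individual, a call present among the raw sequence
    reads is SEQUENCED and a gap filled afterwards is, by definition,
    IMPUTED.  Unsequenced individuals' calls are inferred, stratified by
    whether their family contains any sequenced member.
    """
    if sample.sequenced:
        return (
            ProcessClass.IMPUTED if vcf_call.is_missing else ProcessClass.SEQUENCED
        )
    if family_has_sequenced:
        return ProcessClass.INFERRED_FAM_SEQ
    return ProcessClass.INFERRED_FAM_NOSEQ


def compare_call(gwas: GenotypeCall, geno: GenotypeCall) -> ComparisonOutcome:
    """Compare two calls oriented to the same strand.

    Missing on either side is NOT_COMPARED — varying call rates must not
    masquerade as discrepancies.
    """
    if gwas.is_missing or geno.is_missing:
        return ComparisonOutcome.NOT_COMPARED
    if gwas.code == geno.code:
        return ComparisonOutcome.CONCORDANT
    return ComparisonOutcome.DISCREPANT


def classify_discrepancy(gwas: GenotypeCall, geno: GenotypeCall) -> DiscrepancyType:
    """Zygosity pattern of a discrepant cell (chip call vs completed call)."""
    if compare_call(gwas, geno) is not ComparisonOutcome.DISCREPANT:
        raise ValueError("classify_discrepancy requires a discrepant pair")
    gwas_het, geno_het = gwas.is_het, geno.is_het
    if not gwas_het and geno_het:
        return DiscrepancyType.HOM_TO_HET
    if gwas_het and not geno_het:
        return DiscrepancyType.HET_TO_HOM
    if not gwas_het and not geno_het:
        return DiscrepancyType.HOM_TO_OPP_HOM
    # two differing heterozygotes require >2 alleles at the site
    raise AssertionError(
        "two distinct heterozygotes at one biallelic SNP are impossible"
    )


def call_rate(
    dataset: GenotypeDataset,
    variant_index: int,
    sample_subset: Optional[Iterable[str]] = None,
) -> float:
    """Fraction of the subset with a non-missing call at one variant."""
    if sample_subset is None:
        cols = np.arange(dataset.n_samples)
    else:
        ids = list(sample_subset)
        if not ids:
            raise ValidationError("call_rate requires a non-empty sample subset")
        cols = np.array([dataset.sample_index(s) for s in ids])
    if cols.size == 0:
        raise ValidationError("call_rate requires a non-empty sample subset")
    row = dataset.calls[variant_index, cols]
    return float(np.count_nonzero(row != MISSING_CODE) / cols.size)


# ---------------------------------------------------------------------------
# SNP-set filtering


def select_high_call_rate(
    pairs: Sequence[HarmonizedPair],
    gwas: GenotypeDataset,
    seq_vcf: GenotypeDataset,
    config: ComparisonConfig = ComparisonConfig(),
) -> list[HarmonizedPair]:
    """Retain pairs with call rate >= threshold in BOTH platforms.

    The GWAS call rate is computed over all retained study individuals;
    the sequencing call rate over the sequenced individuals only, using
    the raw (pre-imputation) VCF calls.  The threshold is inclusive —
    "98% or better" keeps a variant at exactly 0.98.  Variants absent
    from the raw sequence data cannot demonstrate the required
    sequencing call rate and are excluded.
    """
    if not pairs:
        return []
    if gwas.n_samples == 0 or seq_vcf.n_samples == 0:
        raise ValidationError("call-rate filtering requires non-empty cohorts")
    thr = config.call_rate_threshold

    left_idx = np.array([p.left_index for p in pairs])
    gwas_rates = (
        np.count_nonzero(gwas.calls[left_idx] != MISSING_CODE, axis=1)
        / gwas.n_samples
    )

    seq_map = {p.variant_key: p.right_index for p in remap_pairs(pairs, seq_vcf)}
    out: list[HarmonizedPair] = []
    for k, pair in enumerate(pairs):
        if gwas_rates[k] < thr:
            continue
        seq_idx = seq_map.get(pair.variant_key)
        if seq_idx is None:
            continue
        seq_rate = (
            np.count_nonzero(seq_vcf.calls[seq_idx] != MISSING_CODE)
            / seq_vcf.n_samples
        )
        if seq_rate >= thr:
            out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Accumulation


_PROCESS_LABELS = {
    ProcessClass.SEQUENCED: "Sequencing",
    ProcessClass.IMPUTED: "Imputation",
    ProcessClass.INFERRED_FAM_SEQ: "Inference-families-with-sequence",
    ProcessClass.INFERRED_FAM_NOSEQ: "Inference-families-without-sequence",
}


def families_with_sequenced(samples: Sequence[SampleRecord]) -> set[str]:
    """Family IDs containing at least one sequenced member."""
    return {s.family_id for s in samples if s.sequenced}


@dataclass
class AccumulationResult:
    """Everything the comparison produced, additively consistent.

    ``outcomes`` and ``processes`` are (n_pairs, n_samples) matrices of
    :class:`ComparisonOutcome` / :class:`ProcessClass` values aligned to
    ``pairs`` x ``sample_ids``.  All summaries are integer-exact
    re-aggregations of those two matrices.
    """

    pairs: list[HarmonizedPair]
    sample_ids: list[str]
    outcomes: np.ndarray
    processes: np.ndarray
    per_individual: dict[str, int]
    per_variant: dict[tuple[str, str], int]
    family_summaries: list[FamilySummary]
    process_summaries: list[ProcessSummary]
    type_tallies: dict[DiscrepancyType, int]
    type_tallies_by_process: dict[ProcessClass, dict[DiscrepancyType, int]]

    @property
    def total_discrepant(self) -> int:
        return int(
            np.count_nonzero(self.outcomes == ComparisonOutcome.DISCREPANT)
        )

    @property
    def total_compared(self) -> int:
        return int(
            np.count_nonzero(self.outcomes != ComparisonOutcome.NOT_COMPARED)
        )

    def process_summary(self, label: str) -> ProcessSummary:
        for s in self.process_summaries:
            if s.process == label:
                return s
        raise KeyError(label)

    @property
    def inference_pooled(self) -> ProcessSummary:
        """The pooled Inference row: both inference strata combined."""
        fam = self.process_summary(_PROCESS_LABELS[ProcessClass.INFERRED_FAM_SEQ])
        nof = self.process_summary(_PROCESS_LABELS[ProcessClass.INFERRED_FAM_NOSEQ])
        return ProcessSummary(
            process="Inference",
            subjects=fam.subjects + nof.subjects,
            genotypes=fam.genotypes + nof.genotypes,
            discrepant=fam.discrepant + nof.discrepant,
        )


def accumulate(
    pairs: Sequence[HarmonizedPair],
    gwas: GenotypeDataset,
    geno: GenotypeDataset,
    seq_vcf: GenotypeDataset,
    samples: Sequence[SampleRecord],
) -> AccumulationResult:
    """Classify every (pair, sample) cell once and aggregate all strata.

    *gwas* defines the comparison sample universe; every universe sample
    must be present in *geno* and in the pedigree.  Both datasets must
    already be oriented onto the same strand.
    """
    by_id = {s.sample_id: s for s in samples}
    missing_ped = [s for s in gwas.samples if s not in by_id]
    if missing_ped:
        raise ValidationError(
            f"samples present in genotype data but absent from pedigree: "
            f"{missing_ped[:5]}"
        )
    universe = list(gwas.samples)
    try:
        geno_cols = np.array([geno.sample_index(s) for s in universe])
    except KeyError as exc:
        raise ValidationError(f"sample missing from completed calls: {exc}")

    fams_with_seq = families_with_sequenced(samples)
    seq_flag = np.array([by_id[s].sequenced for s in universe])
    fam_has_seq = np.array(
        [by_id[s].family_id in fams_with_seq for s in universe]
    )

    left_idx = np.array([p.left_index for p in pairs], dtype=np.int64)
    right_idx = np.array([p.right_index for p in pairs], dtype=np.int64)
    n_pairs = len(pairs)
    G = (
        gwas.calls[left_idx]
        if n_pairs
        else np.empty((0, len(universe)), dtype=np.int8)
    )
    N = (
        geno.calls[right_idx][:, geno_cols]
        if n_pairs
        else np.empty((0, len(universe)), dtype=np.int8)
    )

    # raw sequence-read presence, aligned to (pairs x universe); variants
    # or samples absent from the VCF count as absent reads
    V_present = np.zeros((n_pairs, len(universe)), dtype=bool)
    if n_pairs:
        seq_pairs = {p.variant_key: p.right_index for p in remap_pairs(pairs, seq_vcf)}
        vcf_col = {sid: k for k, sid in enumerate(seq_vcf.samples)}
        uni_cols = np.array(
            [vcf_col.get(s, -1) for s in universe], dtype=np.int64
        )
        covered = uni_cols >= 0
        row_of = np.full(n_pairs, -1, dtype=np.int64)
        for k, p in enumerate(pairs):
            row_of[k] = seq_pairs.get(p.variant_key, -1)
        have_var = row_of >= 0
        if covered.any() and have_var.any():
            sub = seq_vcf.calls[np.ix_(row_of[have_var], uni_cols[covered])]
            block = sub != MISSING_CODE
            V_present[np.ix_(have_var, covered)] = block

    # outcomes
    both_present = (G != MISSING_CODE) & (N != MISSING_CODE)
    outcomes = np.full(
        (n_pairs, len(universe)), ComparisonOutcome.NOT_COMPARED, dtype=np.int8
    )
    outcomes[both_present & (G == N)] = ComparisonOutcome.CONCORDANT
    discrepant = both_present & (G != N)
    outcomes[discrepant] = ComparisonOutcome.DISCREPANT

    # process labels
    processes = np.empty((n_pairs, len(universe)), dtype=np.int8)
    processes[:, seq_flag] = np.where(
        V_present[:, seq_flag], ProcessClass.SEQUENCED, ProcessClass.IMPUTED
    )
    unseq = ~seq_flag
    processes[:, unseq] = np.where(
        fam_has_seq[unseq],
        ProcessClass.INFERRED_FAM_SEQ,
        ProcessClass.INFERRED_FAM_NOSEQ,
    )

    # per-individual and per-variant discrepancy counts
    ind_counts = discrepant.sum(axis=0)
    per_individual = {s: int(c) for s, c in zip(universe, ind_counts)}
    var_counts = discrepant.sum(axis=1)
    per_variant = {
        p.variant_key: int(c) for p, c in zip(pairs, var_counts)
    }

    # family summaries (N counts individuals, compared or not)
    fam_rows: list[FamilySummary] = []
    fam_ids: list[str] = []
    for s in samples:
        if s.family_id not in fam_ids:
            fam_ids.append(s.family_id)
    uni_set = set(universe)
    for fam in fam_ids:
        members = [s for s in samples if s.family_id == fam and s.sample_id in uni_set]
        if not members:
            continue
        n_s = sum(1 for m in members if m.sequenced)
        n_n = len(members) - n_s
        d_s = sum(per_individual[m.sample_id] for m in members if m.sequenced)
        d_n = sum(per_individual[m.sample_id] for m in members if not m.sequenced)
        fam_rows.append(
            FamilySummary(
                family_id=fam, n_seq=n_s, d_seq=d_s, n_nonseq=n_n, d_nonseq=d_n
            )
        )

    # process summaries
    compared = outcomes != ComparisonOutcome.NOT_COMPARED
    proc_rows: list[ProcessSummary] = []
    for pc in ProcessClass:
        mask = processes == pc
        cmp_mask = mask & compared
        genotypes = int(np.count_nonzero(cmp_mask))
        disc = int(np.count_nonzero(mask & discrepant))
        subjects = int(np.count_nonzero(cmp_mask.any(axis=0)))
        proc_rows.append(
            ProcessSummary(
                process=_PROCESS_LABELS[pc],
                subjects=subjects,
                genotypes=genotypes,
                discrepant=disc,
            )
        )

    # discrepancy-type tallies, per process class and pooled
    tallies = {t: 0 for t in DiscrepancyType}
    by_process: dict[ProcessClass, dict[DiscrepancyType, int]] = {
        pc: {t: 0 for t in DiscrepancyType} for pc in ProcessClass
    }
    if n_pairs:
        g_het = np.zeros_like(discrepant)
        n_het = np.zeros_like(discrepant)
        g_het[both_present] = IS_HET[G[both_present]]
        n_het[both_present] = IS_HET[N[both_present]]
        type_masks = {
            DiscrepancyType.HOM_TO_HET: discrepant & ~g_het & n_het,
            DiscrepancyType.HET_TO_HOM: discrepant & g_het & ~n_het,
            DiscrepancyType.HOM_TO_OPP_HOM: discrepant & ~g_het & ~n_het,
            DiscrepancyType.OTHER: discrepant & g_het & n_het,
        }
        for dtype, mask in type_masks.items():
            tallies[dtype] = int(np.count_nonzero(mask))
            for pc in ProcessClass:
                by_process[pc][dtype] = int(
                    np.count_nonzero(mask & (processes == pc))
                )
    if tallies[DiscrepancyType.OTHER]:
        raise AssertionError(
            "discrepant heterozygote/heterozygote cells found at biallelic SNPs"
        )

    return AccumulationResult(
        pairs=list(pairs),
        sample_ids=universe,
        outcomes=outcomes,
        processes=processes,
        per_individual=per_individual,
        per_variant=per_variant,
        family_summaries=fam_rows,
        process_summaries=proc_rows,
        type_tallies=tallies,
        type_tallies_by_process=by_process,
    )


# ---------------------------------------------------------------------------
# Derived statistics


def zero_discrepancy_fraction(
    per_variant_counts: Mapping[tuple[str, str], int] | Mapping[str, int],
) -> float:
    """Fraction of compared variants with zero discrepancies."""
    if not per_variant_counts:
        raise ValidationError("zero_discrepancy_fraction of an empty variant set")
    zeros = sum(1 for c in per_variant_counts.values() if c == 0)
    return zeros / len(per_variant_counts)


def detect_outliers(
    per_individual_counts: Mapping[str, int],
    config: ComparisonConfig = ComparisonConfig(),
) -> list[str]:
    """Flag extreme-discrepancy individuals (sample-swap candidates).

    Scans counts in descending order and flags while the count exceeds
    ``outlier_gap_factor`` times the next-highest count AND is at least
    ``outlier_min_count``; stops at the first individual not flagged.
    The rule formalises "one individual had 11,576 discrepancies, the
    next-highest only 1,880": a large multiplicative gap at a large
    absolute count.
    """
    items = sorted(
        per_individual_counts.items(), key=lambda kv: (-kv[1], kv[0])
    )
    if len(items) < 2:
        return []
    flagged: list[str] = []
    for k in range(len(items) - 1):
        count = items[k][1]
        nxt = items[k + 1][1]
        if count >= config.outlier_min_count and count > config.outlier_gap_factor * nxt:
            flagged.append(items[k][0])
        else:
            break
    return flagged


def remove_samples(
    datasets: Sequence[GenotypeDataset], sample_ids: Iterable[str]
) -> list[GenotypeDataset]:
    """Drop individuals from every dataset (post-outlier-detection).

    Each ID must exist in at least one of the datasets; downstream
    denominators (subjects, call rates) then exclude them everywhere.
    """
    drop = set(sample_ids)
    known = set()
    for ds in datasets:
        known.update(ds.samples)
    unknown = drop - known
    if unknown:
        raise ValidationError(f"cannot remove unknown sample IDs: {sorted(unknown)}")
    out = []
    for ds in datasets:
        keep = [s for s in ds.samples if s not in drop]
        out.append(ds.subset_samples(keep) if len(keep) != ds.n_samples else ds)
    return out


# ---------------------------------------------------------------------------
# Dosage audit


@dataclass
class DosageAuditReport:
    """Cross-check of completed calls against imputation dosages.

    Imputation pipelines blank calls whose dosage is not confidently
    integral, so a *violation* is a cell whose dosage is non-integral
    (beyond tolerance from each of 0, 1, 2) while its completed call is
    present.  The four tallies partition all audited cells by
    (integral?, present?).
    """

    violations: list[tuple[str, str, str, float]]  # (rsid, chrom, sample, dosage)
    nonintegral_blank: int = 0
    nonintegral_present: int = 0
    integral_blank: int = 0
    integral_present: int = 0

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    def to_tsv(self) -> str:
        lines = ["rsid\tchromosome\tsample_id\tdosage"]
        for rsid, chrom, sid, value in self.violations:
            lines.append(f"{rsid}\t{chrom}\t{sid}\t{value:.6g}")
        return "\n".join(lines) + "\n"


def dosage_audit(
    geno: GenotypeDataset,
    dosage: DosageTable,
    config: ComparisonConfig = ComparisonConfig(),
) -> DosageAuditReport:
    """Audit dosage integrality against completed-call presence.

    Audits the (variant, sample) cells shared between the completed calls
    and the dosage table; absent (NA) dosages are skipped.
    """
    tol = config.dosage_integrality_tolerance
    geno_index = geno.variant_key_index()
    geno_col = {sid: k for k, sid in enumerate(geno.samples)}

    report = DosageAuditReport(violations=[])
    sample_cols = [
        (s_d, geno_col[sid])
        for s_d, sid in enumerate(dosage.samples)
        if sid in geno_col
    ]
    for v_d, key in enumerate(dosage.variant_keys):
        rsid, chrom = key
        hits = geno_index.get((rsid, chrom), [])
        if len(hits) != 1:
            continue
        row = geno.calls[hits[0]]
        for s_d, s_g in sample_cols:
            value = dosage.values[v_d, s_d]
            if np.isnan(value):
                continue
            integral = min(abs(value - t) for t in (0.0, 1.0, 2.0)) <= tol
            present = row[s_g] != MISSING_CODE
            if integral and present:
                report.integral_present += 1
            elif integral:
                report.integral_blank += 1
            elif present:
                report.nonintegral_present += 1
                report.violations.append(
                    (rsid, chrom, dosage.samples[s_d], float(value))
                )
            else:
                report.nonintegral_blank += 1
    return report
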