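"""End-to-end comparison pipeline: harmonize, screen outliers, accumulate.

Order of operations: select the comparable SNP set, orient the completed
calls onto the chip strand, detect and remove outlier individuals
(sample-swap candidates) using full-set discrepancy counts, then
re-accumulate over the cleaned cohort for both the full comparison SNPs
and the high-call-rate subset.  Outlier removal before the per-SNP
call-rate filter is the default; both stages are recorded in the run
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .engine import (
    AccumulationResult,
    accumulate,
    detect_outliers,
    remove_samples,
    select_high_call_rate,
    zero_discrepancy_fraction,
)
from .harmonize import (
    HarmonizationResult,
    orient_genotypes,
    select_comparison_snps,
)
from .model import ComparisonConfig, GenotypeDataset, SampleRecord
from .report import RunManifest

__all__ = ["ComparisonRun", "run_comparison"]


@dataclass
class ComparisonRun:
    """Everything one pipeline run produced."""

    harmonization: HarmonizationResult
    outliers: list[str]
    full: AccumulationResult
    high: AccumulationResult
    zero_discrepancy_fraction_high: Optional[float]
    manifest: RunManifest

    @property
    def n_high_call_rate_snps(self) -> int:
        return len(self.high.pairs)


def run_comparison(
    gwas: GenotypeDataset,
    geno: GenotypeDataset,
    seq_vcf: GenotypeDataset,
    pedigree: Sequence[SampleRecord],
    config: ComparisonConfig = ComparisonConfig(),
    remove_outliers: bool = True,
    seed: Optional[int] = None,
) -> ComparisonRun:
    """Run the full GWAS-vs-completed-calls discrepancy evaluation."""
    harm = select_comparison_snps(gwas, geno)
    geno_oriented = orient_genotypes(geno, harm.pairs)

    outliers: list[str] = []
    if remove_outliers and harm.pairs:
        screen = accumulate(harm.pairs, gwas, geno_oriented, seq_vcf, pedigree)
        outliers = detect_outliers(screen.per_individual, config)
        if outliers:
            gwas, geno_oriented, seq_vcf = remove_samples(
                [gwas, geno_oriented, seq_vcf], outliers
            )

    full = accumulate(harm.pairs, gwas, geno_oriented, seq_vcf, pedigree)
    high_pairs = select_high_call_rate(harm.pairs, gwas, seq_vcf, config)
    high = accumulate(high_pairs, gwas, geno_oriented, seq_vcf, pedigree)
    zero_frac = (
        zero_discrepancy_fraction(high.per_variant) if high.pairs else None
    )

    c = harm.counters
    manifest = RunManifest(
        config={
            "call_rate_threshold": config.call_rate_threshold,
            "outlier_gap_factor": config.outlier_gap_factor,
            "outlier_min_count": config.outlier_min_count,
            "dosage_integrality_tolerance": config.dosage_integrality_tolerance,
            "remove_outliers": remove_outliers,
            "outlier_removal_order": "before-call-rate-filter",
        },
        candidate_rsids=c.candidates,
        after_duplicates=c.candidates - c.duplicate,
        after_chromosome=c.candidates - c.duplicate - c.chromosome_mismatch,
        after_ambiguous=(
            c.candidates - c.duplicate - c.chromosome_mismatch - c.ambiguous
        ),
        retained=c.retained,
        high_call_rate=len(high_pairs),
        samples_removed=list(outliers),
        seed=seed,
        tool_version=__version__,
    )
    manifest.validate()
    return ComparisonRun(
        harmonization=harm,
        outliers=outliers,
        full=full,
        high=high,
        zero_discrepancy_fraction_high=zero_frac,
        manifest=manifest,
    )
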