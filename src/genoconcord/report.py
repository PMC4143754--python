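"""Rendering of family and process tables, and the run manifest.

TSV is the canonical machine-checkable report format; all rounding is
decimal half-up (so 5287/20 renders 264.4, not the 264.3 that binary
floats would give), with D/N ratios to 1 decimal and percentages to 2
decimals.  Internal accumulation stays in exact integers; rounding
happens only here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .engine import FamilySummary, ProcessSummary
from .errors import ValidationError

__all__ = [
    "round_half_up",
    "format_ratio",
    "format_percent",
    "render_family_table",
    "render_process_table",
    "parse_table",
    "RunManifest",
]


def round_half_up(numerator: int, denominator: int, decimals: int) -> Decimal:
    """Exact decimal quotient rounded half-up to *decimals* places."""
    if denominator == 0:
        raise ZeroDivisionError("round_half_up with zero denominator")
    q = Decimal(numerator) / Decimal(denominator)
    return q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)


def format_ratio(d: int, n: int, decimals: int = 1) -> str:
    """D/N as printed in family tables (1 decimal, half-up); '' when N=0."""
    if n == 0:
        return ""
    return str(round_half_up(d, n, decimals))


def format_percent(discrepant: int, genotypes: int, decimals: int = 2) -> str:
    """100*discrepant/genotypes, half-up; '0.00' for an empty cell set."""
    if genotypes == 0:
        return str(Decimal(0).quantize(Decimal(1).scaleb(-decimals)))
    return str(round_half_up(100 * discrepant, genotypes, decimals))


_FAMILY_HEADER = [
    "Fam_ID",
    "N_seq", "D_seq", "D/N_seq",
    "N_nonseq", "D_nonseq", "D/N_nonseq",
    "N_all", "D_all", "D/N_all",
]


def _stratum_ratio(s: FamilySummary, stratum: str) -> float:
    value = {
        "sequenced": s.d_over_n_seq,
        "nonsequenced": s.d_over_n_nonseq,
        "all": s.d_over_n_all,
    }[stratum]
    return value if value is not None else float("-inf")


def render_family_table(
    summaries: Sequence[FamilySummary], sort_key: str = "all"
) -> str:
    """Family-stratified discrepancy table as TSV.

    One row per family with (N, D, D/N) for the sequenced, nonsequenced
    and all-member strata; strata with no members render empty cells.
    Rows sort descending by the chosen stratum's D/N; a TOTAL row sums
    N and D columns.
    """
    if sort_key not in ("sequenced", "nonsequenced", "all"):
        raise ValidationError(f"unknown sort stratum: {sort_key}")
    rows = sorted(
        summaries,
        key=lambda s: (-_stratum_ratio(s, sort_key), s.family_id),
    )
    lines = ["\t".join(_FAMILY_HEADER)]
    for s in rows:
        cells = [s.family_id]
        for n, d in ((s.n_seq, s.d_seq), (s.n_nonseq, s.d_nonseq),
                     (s.n_all, s.d_all)):
            if n == 0:
                cells.extend(("", "", ""))
            else:
                cells.extend((str(n), str(d), format_ratio(d, n)))
        lines.append("\t".join(cells))
    tot = {
        "n_seq": sum(s.n_seq for s in rows),
        "d_seq": sum(s.d_seq for s in rows),
        "n_nonseq": sum(s.n_nonseq for s in rows),
        "d_nonseq": sum(s.d_nonseq for s in rows),
    }
    n_all = tot["n_seq"] + tot["n_nonseq"]
    d_all = tot["d_seq"] + tot["d_nonseq"]
    lines.append(
        "\t".join(
            [
                "TOTAL",
                str(tot["n_seq"]), str(tot["d_seq"]),
                format_ratio(tot["d_seq"], tot["n_seq"]),
                str(tot["n_nonseq"]), str(tot["d_nonseq"]),
                format_ratio(tot["d_nonseq"], tot["n_nonseq"]),
                str(n_all), str(d_all), format_ratio(d_all, n_all),
            ]
        )
    )
    return "\n".join(lines) + "\n"


_PROCESS_ORDER = [
    "Imputation",
    "Sequencing",
    "Inference",
    "Inference-families-with-sequence",
    "Inference-families-without-sequence",
]


def render_process_table(summaries: Sequence[ProcessSummary]) -> str:
    """By-process discrepancy table as TSV.

    Rows follow the canonical order (Imputation, Sequencing, pooled
    Inference, then the two inference strata); genotype counts carry
    thousands separators, percentages 2 decimals.
    """
    by_name = {s.process: s for s in summaries}
    lines = ["Type\tSubjects\tGenotypes (N)\t% Discrepant"]
    for name in _PROCESS_ORDER:
        s = by_name.get(name)
        if s is None:
            continue
        lines.append(
            f"{s.process}\t{s.subjects}\t{s.genotypes:,}\t"
            f"{format_percent(s.discrepant, s.genotypes)}"
        )
    return "\n".join(lines) + "\n"


def parse_table(text: str) -> list[dict[str, str]]:
    """Parse a rendered TSV table back into header-keyed row dicts."""
    lines = [ln for ln in text.splitlines() if ln]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


@dataclass
class RunManifest:
    """Provenance and telescoping filter counts for one comparison run.

    Each filtering stage retains a subset of the previous one:
    candidate rsID matches -> after duplicate removal -> after
    chromosome check -> after dropping strand-ambiguous SNPs -> retained
    comparison SNPs -> high-call-rate subset.
    """

    inputs: dict[str, str] = field(default_factory=dict)
    config: dict[str, object] = field(default_factory=dict)
    candidate_rsids: int = 0
    after_duplicates: int = 0
    after_chromosome: int = 0
    after_ambiguous: int = 0
    retained: int = 0
    high_call_rate: int = 0
    samples_removed: list[str] = field(default_factory=list)
    seed: Optional[int] = None
    tool_version: str = ""

    def stage_counts(self) -> list[tuple[str, int]]:
        return [
            ("candidate_rsids", self.candidate_rsids),
            ("after_duplicates", self.after_duplicates),
            ("after_chromosome", self.after_chromosome),
            ("after_ambiguous", self.after_ambiguous),
            ("retained", self.retained),
            ("high_call_rate", self.high_call_rate),
        ]

    def validate(self) -> None:
        previous = None
        for name, count in self.stage_counts():
            if count < 0:
                raise ValidationError(f"manifest stage {name} is negative")
            if previous is not None and count > previous:
                raise ValidationError(
                    f"manifest stage {name} ({count}) exceeds its "
                    f"predecessor ({previous})"
                )
            previous = count

    def render(self) -> str:
        self.validate()
        lines = []
        for key, value in sorted(self.inputs.items()):
            lines.append(f"input.{key}\t{value}")
        for key, value in sorted(self.config.items()):
            lines.append(f"config.{key}\t{value}")
        for name, count in self.stage_counts():
            lines.append(f"stage.{name}\t{count}")
        lines.append(f"samples_removed\t{','.join(self.samples_removed) or '-'}")
        lines.append(f"seed\t{self.seed if self.seed is not None else '-'}")
        lines.append(f"tool_version\t{self.tool_version}")
        return "\n".join(lines) + "\n"
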