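"""Synthetic pedigree-cohort generator with a configurable error model.

Emulates a family-based sequencing study in which every individual has
GWAS-chip genotypes, roughly half of the members of most families are
whole-genome sequenced (a few families have no sequenced members at
all), and the final completed genotype matrix combines raw sequence
reads, imputed fills for sequenced individuals' gaps, and inferred calls
for unsequenced relatives.

The imputation/inference software is not re-run; it is modelled as an
error channel on gene-dropped truth, because the downstream discrepancy
analysis depends only on the *distribution* of errors:

* imputed fills are wrong with probability ``imputation_error_rate``,
  and a fraction ``het_bias`` of all wrong imputed calls are
  homozygote-truth cells miscalled heterozygous (the signature failure
  mode of likelihood-based pedigree imputation, where a heterozygote is
  compatible with every configuration of relatives); the remaining
  error mass falls on heterozygous-truth cells miscalled as a uniform
  homozygote;
* inferred calls are wrong with probability
  ``inference_error_rate_famseq``, doubled (``inference_noseq_multiplier``)
  in families with no sequenced members, the wrong genotype drawn
  uniformly from the two alternatives;
* a fraction of filled calls is blanked (left missing) to emulate
  pipelines that blank low-confidence fills, and blanked cells can be
  emitted with nonintegral dosages while present calls always carry
  integral dosages;
* chip variants can be reported on the opposite strand (``flip_fraction``)
  and a fraction of variants are strand-ambiguous A/T or C/G SNPs, so
  harmonization has real work to do;
* ``swap_samples`` pairs emulate specimen mix-ups: the first sample's
  chip data are replaced by the second's (one-way — a reciprocal swap
  would corrupt two individuals equally, whereas the phenomenon being
  modelled is a single corrupted specimen standing out from the cohort).

A ground-truth ledger records every cell's true genotype, process label
and injection flag so recovery can be verified exactly.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .io import (
    write_dosage,
    write_matrix_tsv,
    write_ped_map,
    write_pedigree,
    write_vcf,
)
from .model import (
    FLIP_CODE,
    MISSING_CODE,
    Allele,
    DosageTable,
    GenotypeDataset,
    ProcessClass,
    SampleRecord,
    VariantRecord,
    encode_pair,
)

__all__ = [
    "SimulationConfig",
    "TruthData",
    "GroundTruthLedger",
    "Scenario",
    "simulate_pedigrees",
    "gene_drop",
    "make_observed_datasets",
    "simulate_scenario",
    "write_scenario",
    "pick_unrelated_pair",
]

_NONAMBIGUOUS_PAIRS = [
    (Allele.A, Allele.C),
    (Allele.A, Allele.G),
    (Allele.C, Allele.T),
    (Allele.G, Allele.T),
]
_AMBIGUOUS_PAIRS = [(Allele.A, Allele.T), (Allele.C, Allele.G)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and error-model parameters of a synthetic scenario.

    The defaults describe the emulated study: 20 multi-generation
    families totalling roughly 950 members, four families with no
    sequenced members and about half of each remaining family sequenced;
    per-call chip missingness of 0.5% and sequence missingness of 0.2%
    (so ~0.2% of a sequenced individual's completed calls are imputed);
    a 0.03% chip-vs-read disagreement rate; a 25% imputation error rate
    of which 98.6% are homozygote->heterozygote miscalls; and inference
    error rates of 0.07% (families with sequence) doubled in families
    without.  Variant count is scaled to thousands rather than millions
    so end-to-end runs stay interactive.
    """

    n_families: int = 20
    family_size_range: tuple[int, int] = (25, 70)
    n_generations: int = 4
    n_variants: int = 5000
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    chip_fraction: float = 0.5
    gwas_missing_rate: float = 0.005
    seq_missing_rate: float = 0.002
    gwas_error_rate: float = 0.0003
    imputation_error_rate: float = 0.25
    het_bias: float = 0.986
    inference_error_rate_famseq: float = 0.0007
    inference_noseq_multiplier: float = 2.0
    sequenced_fraction: float = 0.5
    n_noseq_families: int = 4
    flip_fraction: float = 0.3
    ambiguous_fraction: float = 0.15
    imputed_blank_rate: float = 0.02
    nonintegral_dosage_for_blanked: bool = True
    swap_samples: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "chip_fraction": self.chip_fraction,
            "gwas_missing_rate": self.gwas_missing_rate,
            "seq_missing_rate": self.seq_missing_rate,
            "gwas_error_rate": self.gwas_error_rate,
            "imputation_error_rate": self.imputation_error_rate,
            "het_bias": self.het_bias,
            "inference_error_rate_famseq": self.inference_error_rate_famseq,
            "sequenced_fraction": self.sequenced_fraction,
            "flip_fraction": self.flip_fraction,
            "ambiguous_fraction": self.ambiguous_fraction,
            "imputed_blank_rate": self.imputed_blank_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.inference_noseq_multiplier <= 0:
            raise ValidationError("inference_noseq_multiplier must be > 0")
        lo, hi = self.family_size_range
        if lo > hi or lo < 2:
            raise ValidationError(
                f"family_size_range {self.family_size_range} is infeasible "
                f"(need at least a founder couple)"
            )
        if self.n_generations < 1:
            raise ValidationError("n_generations must be >= 1")
        if self.n_noseq_families > self.n_families:
            raise ValidationError("n_noseq_families exceeds n_families")
        fmin, fmax = self.allele_freq_range
        if not (0.0 <= fmin <= fmax <= 1.0):
            raise ValidationError("allele_freq_range must satisfy 0<=min<=max<=1")

    # hierarchical stream indices: one global seed feeds independent
    # child streams so sub-processes are separately reproducible
    _STREAMS = {
        "pedigree": 0,
        "genedrop": 1,
        "chip": 2,
        "gwas": 3,
        "seq": 4,
        "impute": 5,
        "infer": 6,
        "dosage": 7,
    }

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(self._STREAMS))
        return np.random.default_rng(children[self._STREAMS[stream]])

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["family_size_range"] = list(self.family_size_range)
        data["allele_freq_range"] = list(self.allele_freq_range)
        data["swap_samples"] = [list(p) for p in self.swap_samples]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "family_size_range" in data:
            data["family_size_range"] = tuple(data["family_size_range"])
        if "allele_freq_range" in data:
            data["allele_freq_range"] = tuple(data["allele_freq_range"])
        if "swap_samples" in data:
            data["swap_samples"] = tuple(
                tuple(p) for p in data["swap_samples"]
            )
        return cls(**data)


# ---------------------------------------------------------------------------
# Pedigrees


def simulate_pedigrees(config: SimulationConfig) -> list[SampleRecord]:
    """Generate multi-generation pedigrees with sequenced-status flags.

    Families grow breadth-first from a founder couple: couples bear 1-4
    children, and children below the final generation marry an
    in-migrating founder spouse with probability 0.7.  Exactly
    ``n_noseq_families`` families get zero sequenced members; in the
    rest, ``sequenced_fraction`` of members (at least one) are flagged.
    Samples are listed parents-before-children.
    """
    rng = config.rng("pedigree")
    lo, hi = config.family_size_range
    noseq = set(
        rng.choice(config.n_families, size=config.n_noseq_families, replace=False)
    )
    records: list[SampleRecord] = []
    for fi in range(config.n_families):
        fam = f"F{fi + 1:02d}"
        target = int(rng.integers(lo, hi + 1))
        serial = 0

        def new_id() -> str:
            nonlocal serial
            serial += 1
            return f"{fam}-{serial:03d}"

        members: list[tuple[str, Optional[str], Optional[str]]] = []
        if config.n_generations == 1:
            for _ in range(target):
                members.append((new_id(), None, None))
        else:
            father, mother = new_id(), new_id()
            members = [(father, None, None), (mother, None, None)]
            couples: list[tuple[str, str, int]] = [(father, mother, 0)]
            qi = 0
            while len(members) < target and qi < len(couples):
                fa, mo, gen = couples[qi]
                qi += 1
                for _ in range(int(rng.integers(1, 5))):
                    if len(members) >= target:
                        break
                    child = new_id()
                    members.append((child, fa, mo))
                    deeper_ok = gen + 1 < config.n_generations - 1
                    if deeper_ok and len(members) < target and rng.random() < 0.7:
                        spouse = new_id()
                        members.append((spouse, None, None))
                        couples.append((child, spouse, gen + 1))
            # top up with extra children of existing couples
            eligible = [
                (fa, mo) for fa, mo, gen in couples
                if gen + 1 <= config.n_generations - 1
            ]
            while len(members) < target:
                fa, mo = eligible[int(rng.integers(len(eligible)))]
                members.append((new_id(), fa, mo))

        if fi in noseq:
            sequenced_idx: set[int] = set()
        else:
            k = max(1, round(config.sequenced_fraction * len(members)))
            sequenced_idx = set(
                int(i) for i in rng.choice(len(members), size=k, replace=False)
            )
        for m_idx, (sid, fa, mo) in enumerate(members):
            records.append(
                SampleRecord(
                    sample_id=sid,
                    family_id=fam,
                    father_id=fa,
                    mother_id=mo,
                    sequenced=m_idx in sequenced_idx,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Gene dropping


@dataclass
class TruthData:
    """Complete error-free genotypes: minor-allele counts down a pedigree."""

    variants: list[VariantRecord]
    samples: list[str]
    counts: np.ndarray  # (n_variants, n_samples) of allele_b counts 0/1/2
    freqs: np.ndarray  # founder allele_b frequency per variant

    def code_lut(self) -> np.ndarray:
        """(n_variants, 3) lookup: allele_b count -> genotype pair code."""
        lut = np.empty((len(self.variants), 3), dtype=np.int8)
        for i, v in enumerate(self.variants):
            lut[i, 0] = encode_pair(v.allele_a, v.allele_a)
            lut[i, 1] = encode_pair(v.allele_a, v.allele_b)
            lut[i, 2] = encode_pair(v.allele_b, v.allele_b)
        return lut

    def to_dataset(self) -> GenotypeDataset:
        lut = self.code_lut()
        calls = lut[np.arange(len(self.variants))[:, None], self.counts]
        return GenotypeDataset(
            variants=list(self.variants), samples=list(self.samples), calls=calls
        )


def gene_drop(
    pedigree: Sequence[SampleRecord], config: SimulationConfig
) -> TruthData:
    """Drop founder alleles down the pedigrees under Hardy-Weinberg.

    Founders draw their minor-allele count Binomial(2, f) at each
    variant; every child receives one uniformly chosen allele from each
    parent.  Truth has no missingness.
    """
    rng = config.rng("genedrop")
    n_var = config.n_variants
    fmin, fmax = config.allele_freq_range
    freqs = rng.uniform(fmin, fmax, size=n_var)

    amb = rng.random(n_var) < config.ambiguous_fraction
    variants: list[VariantRecord] = []
    per_chrom = -(-n_var // 22)  # ceil division: variants per chromosome
    for i in range(n_var):
        if amb[i]:
            pair = _AMBIGUOUS_PAIRS[int(rng.integers(2))]
        else:
            pair = _NONAMBIGUOUS_PAIRS[int(rng.integers(4))]
        chrom = str(i // per_chrom + 1)
        pos = 10_000 + 500 * (i % per_chrom)
        variants.append(
            VariantRecord(
                chromosome=chrom,
                position=pos,
                rsid=f"rs{1_000_000 + i}",
                allele_a=pair[0],
                allele_b=pair[1],
            )
        )

    col = {s.sample_id: k for k, s in enumerate(pedigree)}
    counts = np.zeros((n_var, len(pedigree)), dtype=np.int8)
    for s in pedigree:
        k = col[s.sample_id]
        if s.is_founder:
            counts[:, k] = rng.binomial(2, freqs).astype(np.int8)
        else:
            fa = counts[:, col[s.father_id]]
            mo = counts[:, col[s.mother_id]]
            t_fa = (rng.random(n_var) < fa / 2.0).astype(np.int8)
            t_mo = (rng.random(n_var) < mo / 2.0).astype(np.int8)
            counts[:, k] = t_fa + t_mo
    return TruthData(
        variants=variants,
        samples=[s.sample_id for s in pedigree],
        counts=counts,
        freqs=freqs,
    )


# ---------------------------------------------------------------------------
# Observed datasets


@dataclass
class GroundTruthLedger:
    """Per-cell ground truth for validating the evaluation pipeline.

    Aligned to the truth variant list x the full sample list:
    ``true_counts`` are error-free minor-allele counts,
    ``process_labels`` hold the :class:`ProcessClass` that produced each
    completed call, and ``injected`` marks cells whose emitted completed
    call differs from truth (never True for blanked cells).
    """

    variants: list[VariantRecord]
    samples: list[str]
    true_counts: np.ndarray
    process_labels: np.ndarray
    injected: np.ndarray
    swap_records: list[tuple[str, str]]

    def process_by_key(self) -> dict[tuple[str, str], np.ndarray]:
        return {
            (v.rsid, v.chrom_norm): self.process_labels[i]
            for i, v in enumerate(self.variants)
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rsid\tchromosome\tsample_id\ttrue_count\tprocess\tinjected\n")
            for i, v in enumerate(self.variants):
                for k, sid in enumerate(self.samples):
                    fh.write(
                        f"{v.rsid}\t{v.chrom_norm}\t{sid}\t"
                        f"{int(self.true_counts[i, k])}\t"
                        f"{ProcessClass(int(self.process_labels[i, k])).name}\t"
                        f"{int(self.injected[i, k])}\n"
                    )


@dataclass
class Scenario:
    """A complete simulated study: inputs, observed files, ground truth."""

    config: SimulationConfig
    pedigree: list[SampleRecord]
    truth: TruthData
    gwas: GenotypeDataset
    seq_vcf: GenotypeDataset
    geno: GenotypeDataset
    dosage: DosageTable
    ledger: GroundTruthLedger


def _uniform_wrong(
    counts: np.ndarray, mask: np.ndarray, rng: np.random.Generator
) -> None:
    """In-place: replace masked genotype counts by a uniform other genotype."""
    n = int(mask.sum())
    if n == 0:
        return
    shift = rng.integers(1, 3, size=n).astype(np.int8)
    counts[mask] = (counts[mask] + shift) % 3


def make_observed_datasets(
    truth: TruthData,
    pedigree: Sequence[SampleRecord],
    config: SimulationConfig,
) -> tuple[GenotypeDataset, GenotypeDataset, GenotypeDataset, DosageTable, GroundTruthLedger]:
    """Derive the GWAS, raw-sequence and completed datasets from truth.

    Returns ``(gwas, seq_vcf, geno, dosage, ledger)``.  See the module
    docstring for the error model.
    """
    n_var = len(truth.variants)
    n_all = len(truth.samples)
    col = {sid: k for k, sid in enumerate(truth.samples)}
    by_id = {s.sample_id: s for s in pedigree}
    lut = truth.code_lut()
    row_idx = np.arange(n_var)

    # ---- GWAS chip -------------------------------------------------------
    chip_rng = config.rng("chip")
    n_chip = max(1, round(config.chip_fraction * n_var))
    chip_idx = np.sort(chip_rng.choice(n_var, size=n_chip, replace=False))
    amb_chip = np.array(
        [
            truth.variants[i].allele_set
            in (frozenset((Allele.A, Allele.T)), frozenset((Allele.C, Allele.G)))
            for i in chip_idx
        ]
    )
    flip_mask = (chip_rng.random(n_chip) < config.flip_fraction) & ~amb_chip

    gwas_rng = config.rng("gwas")
    gwas_counts = truth.counts[chip_idx].copy()
    err = gwas_rng.random(gwas_counts.shape) < config.gwas_error_rate
    _uniform_wrong(gwas_counts, err, gwas_rng)
    miss = gwas_rng.random(gwas_counts.shape) < config.gwas_missing_rate

    gwas_calls = lut[chip_idx[:, None], gwas_counts]
    gwas_calls[miss] = MISSING_CODE

    swap_records: list[tuple[str, str]] = []
    for target, donor in config.swap_samples:
        if target not in col or donor not in col:
            raise ValidationError(
                f"swap pair ({target}, {donor}) not in the cohort"
            )
        gwas_calls[:, col[target]] = gwas_calls[:, col[donor]]
        swap_records.append((target, donor))

    gwas_variants: list[VariantRecord] = []
    for k, i in enumerate(chip_idx):
        v = truth.variants[int(i)]
        gwas_variants.append(v.complemented() if flip_mask[k] else v)
    if flip_mask.any():
        rows = np.where(flip_mask)[0]
        block = gwas_calls[rows]
        present = block != MISSING_CODE
        block[present] = FLIP_CODE[block[present]]
        gwas_calls[rows] = block
    gwas = GenotypeDataset(
        variants=gwas_variants, samples=list(truth.samples), calls=gwas_calls
    )

    # ---- raw sequence reads ---------------------------------------------
    seq_rng = config.rng("seq")
    seq_samples = [s.sample_id for s in pedigree if s.sequenced]
    seq_cols = np.array([col[s] for s in seq_samples], dtype=np.int64)
    if seq_cols.size:
        seq_counts = truth.counts[:, seq_cols]
        seq_calls = lut[row_idx[:, None], seq_counts]
        seq_missing = seq_rng.random(seq_calls.shape) < config.seq_missing_rate
        seq_calls[seq_missing] = MISSING_CODE
    else:
        seq_calls = np.empty((n_var, 0), dtype=np.int8)
        seq_missing = np.empty((n_var, 0), dtype=bool)
    seq_vcf = GenotypeDataset(
        variants=list(truth.variants), samples=seq_samples, calls=seq_calls
    )

    # ---- completed calls (GENO) -----------------------------------------
    geno_counts = truth.counts.copy()
    process = np.empty((n_var, n_all), dtype=np.int8)
    blanked = np.zeros((n_var, n_all), dtype=bool)

    fams_with_seq = {s.family_id for s in pedigree if s.sequenced}

    # sequenced individuals: reads pass through; gaps are imputed
    imp_rng = config.rng("impute")
    if seq_cols.size:
        process[:, seq_cols] = ProcessClass.SEQUENCED
        imputed = np.zeros((n_var, n_all), dtype=bool)
        imputed[:, seq_cols] = seq_missing
        process[imputed] = ProcessClass.IMPUTED

        truth_imputed = truth.counts[imputed]
        hom = truth_imputed != 1
        n_hom, n_het = int(hom.sum()), int((~hom).sum())
        total_err = config.imputation_error_rate * (n_hom + n_het)
        # split the error budget so that a fraction het_bias of all wrong
        # imputed calls are hom-truth cells miscalled heterozygous
        p_hom = min(1.0, config.het_bias * total_err / n_hom) if n_hom else 0.0
        p_het = (
            min(1.0, (1.0 - config.het_bias) * total_err / n_het)
            if n_het
            else 0.0
        )
        u = imp_rng.random(truth_imputed.shape)
        new_vals = truth_imputed.copy()
        hom_err = hom & (u < p_hom)
        new_vals[hom_err] = 1
        het_err = ~hom & (u < p_het)
        new_vals[het_err] = 2 * (
            imp_rng.random(int(het_err.sum())) < 0.5
        ).astype(np.int8)
        geno_counts[imputed] = new_vals
        blanked[imputed] = imp_rng.random(truth_imputed.shape) < config.imputed_blank_rate

    # unsequenced individuals: inferred, stratified by family sequencing
    inf_rng = config.rng("infer")
    unseq_cols = np.array(
        [col[s.sample_id] for s in pedigree if not s.sequenced], dtype=np.int64
    )
    if unseq_cols.size:
        rates = np.array(
            [
                config.inference_error_rate_famseq
                * (
                    1.0
                    if by_id[truth.samples[c]].family_id in fams_with_seq
                    else config.inference_noseq_multiplier
                )
                for c in unseq_cols
            ]
        )
        fam_seq_flags = np.array(
            [by_id[truth.samples[c]].family_id in fams_with_seq for c in unseq_cols]
        )
        process[:, unseq_cols[fam_seq_flags]] = ProcessClass.INFERRED_FAM_SEQ
        process[:, unseq_cols[~fam_seq_flags]] = ProcessClass.INFERRED_FAM_NOSEQ

        sub = geno_counts[:, unseq_cols]
        err = inf_rng.random(sub.shape) < rates[None, :]
        _uniform_wrong(sub, err, inf_rng)
        geno_counts[:, unseq_cols] = sub
        blanked[:, unseq_cols] = (
            inf_rng.random(sub.shape) < config.imputed_blank_rate
        )

    geno_calls = lut[row_idx[:, None], geno_counts]
    geno_calls[blanked] = MISSING_CODE
    geno = GenotypeDataset(
        variants=list(truth.variants), samples=list(truth.samples),
        calls=geno_calls,
    )

    # ---- dosage ----------------------------------------------------------
    dos_rng = config.rng("dosage")
    values = geno_counts.astype(np.float64)
    if config.nonintegral_dosage_for_blanked:
        n_blank = int(blanked.sum())
        delta = dos_rng.uniform(0.001, 0.4, size=n_blank)
        sign = np.where(
            values[blanked] == 0,
            1.0,
            np.where(
                values[blanked] == 2,
                -1.0,
                np.where(dos_rng.random(n_blank) < 0.5, 1.0, -1.0),
            ),
        )
        values[blanked] = values[blanked] + sign * delta
    else:
        values[blanked] = np.nan
    dosage = DosageTable(
        variant_keys=[(v.rsid, v.chrom_norm) for v in truth.variants],
        samples=list(truth.samples),
        values=values,
    )

    injected = (geno_counts != truth.counts) & ~blanked
    ledger = GroundTruthLedger(
        variants=list(truth.variants),
        samples=list(truth.samples),
        true_counts=truth.counts,
        process_labels=process,
        injected=injected,
        swap_records=swap_records,
    )
    return gwas, seq_vcf, geno, dosage, ledger


def simulate_scenario(config: SimulationConfig) -> Scenario:
    """Run the full generator: pedigree, truth, observed datasets, ledger."""
    pedigree = simulate_pedigrees(config)
    truth = gene_drop(pedigree, config)
    gwas, seq_vcf, geno, dosage, ledger = make_observed_datasets(
        truth, pedigree, config
    )
    return Scenario(
        config=config,
        pedigree=pedigree,
        truth=truth,
        gwas=gwas,
        seq_vcf=seq_vcf,
        geno=geno,
        dosage=dosage,
        ledger=ledger,
    )


def pick_unrelated_pair(
    pedigree: Sequence[SampleRecord], seed: int = 0
) -> tuple[str, str]:
    """Deterministically pick two individuals from different families."""
    rng = np.random.default_rng(seed)
    fams: dict[str, list[str]] = {}
    for s in pedigree:
        fams.setdefault(s.family_id, []).append(s.sample_id)
    fam_ids = sorted(fams)
    if len(fam_ids) < 2:
        raise ValidationError("need at least two families for an unrelated pair")
    fa, fb = rng.choice(len(fam_ids), size=2, replace=False)
    a = fams[fam_ids[int(fa)]][int(rng.integers(len(fams[fam_ids[int(fa)]])))]
    b = fams[fam_ids[int(fb)]][int(rng.integers(len(fams[fam_ids[int(fb)]])))]
    return a, b


# ---------------------------------------------------------------------------
# Scenario persistence


def write_scenario(scenario: Scenario, out_dir) -> dict[str, str]:
    """Write a self-contained scenario directory.

    Emits the sequence VCF, GWAS PED/MAP, completed-calls matrix TSV,
    dosage text + variant sidecar, pedigree TSV, ground-truth ledger TSV
    and the generating config YAML.  Returns the path map.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create scenario directory {out}: {exc}") from exc
    paths = {
        "pedigree": str(out / "pedigree.tsv"),
        "sequence_vcf": str(out / "sequence.vcf"),
        "gwas_ped": str(out / "gwas.ped"),
        "gwas_map": str(out / "gwas.map"),
        "geno": str(out / "geno.tsv"),
        "dosage": str(out / "dosage.txt"),
        "dosage_snps": str(out / "dosage.snps"),
        "ledger": str(out / "ledger.tsv"),
        "config": str(out / "config.yaml"),
    }
    write_pedigree(scenario.pedigree, paths["pedigree"])
    write_vcf(scenario.seq_vcf, paths["sequence_vcf"])
    write_ped_map(
        scenario.gwas, paths["gwas_ped"], paths["gwas_map"], scenario.pedigree
    )
    write_matrix_tsv(scenario.geno, paths["geno"])
    write_dosage(scenario.dosage, paths["dosage"], paths["dosage_snps"])
    scenario.ledger.write_tsv(paths["ledger"])
    scenario.config.to_yaml(paths["config"])
    return paths
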