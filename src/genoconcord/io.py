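"""Readers and writers for the on-disk genotype representations.

Supported formats:

* VCF 4.x with a GT FORMAT field (sequence data; read via cyvcf2, written
  as plain text).  Only biallelic SNP records are loaded; multiallelic,
  indel and otherwise non-SNP records are skipped and counted.
* PLINK-style text PED/MAP (GWAS chip exports).
* A genotype-matrix TSV dialect for the completed ("GENO") calls:
  header ``chrom pos rsid a1 a2 <sample>...``, cells ``AC``-style
  two-letter genotypes or ``NA``.
* MaCH-style dosage text (one row per sample: ``<id> DOSE d1 d2 ...``)
  with a sidecar listing the variant order.
* A pedigree TSV: ``family_id sample_id father_id mother_id sequenced``.

Half-calls (one allele missing) are normalised to MISSING everywhere and
counted in the parse log: the comparison rule only distinguishes "called
in both datasets" from anything else, and a half-call is not a usable
genotype.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np
from cyvcf2 import VCF

from .errors import ParseError, ValidationError
from .model import (
    MISSING_CODE,
    Allele,
    DosageTable,
    GenotypeDataset,
    SampleRecord,
    VariantRecord,
    encode_pair,
    validate_pedigree,
)

PathLike = Union[str, os.PathLike]

__all__ = [
    "ParseLog",
    "read_vcf",
    "write_vcf",
    "read_ped_map",
    "write_ped_map",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_dosage",
    "write_dosage",
    "read_pedigree",
    "write_pedigree",
]

_VALID_BASES = {"A", "C", "G", "T"}


@dataclass
class ParseLog:
    """Counters accumulated while reading a file.

    skipped_non_snp counts indels / symbolic / non-ACGT records;
    skipped_multiallelic counts records with more than one ALT allele;
    half_calls counts genotypes with exactly one missing allele
    (normalised to MISSING); monomorphic_variants counts chip variants
    whose second allele had to be invented because only one allele was
    observed in the data.
    """

    skipped_non_snp: int = 0
    skipped_multiallelic: int = 0
    half_calls: int = 0
    monomorphic_variants: int = 0

    @property
    def skipped(self) -> int:
        return self.skipped_non_snp + self.skipped_multiallelic


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: PathLike, log: Optional[ParseLog] = None) -> GenotypeDataset:
    """Load biallelic SNP genotypes from a VCF 4.x file.

    Multiallelic and non-SNP records are skipped (counted in *log*);
    ``./.`` and half-missing GT values become MISSING.  Phase separators
    are accepted and ignored.
    """
    log = log if log is not None else ParseLog()
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read VCF: no such file: {path}")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise IOError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            alts = [a for a in rec.ALT if a is not None]
            if len(alts) != 1:
                log.skipped_multiallelic += 1
                continue
            ref, alt = rec.REF, alts[0]
            if (
                len(ref) != 1
                or len(alt) != 1
                or ref.upper() not in _VALID_BASES
                or alt.upper() not in _VALID_BASES
            ):
                log.skipped_non_snp += 1
                continue
            a_ref = Allele(ref.upper())
            a_alt = Allele(alt.upper())
            rsid = rec.ID if rec.ID not in (None, ".", "") else None
            variants.append(
                VariantRecord(
                    chromosome=str(rec.CHROM),
                    position=int(rec.POS),
                    rsid=rsid,
                    allele_a=a_ref,
                    allele_b=a_alt,
                )
            )
            # rec.genotypes: per sample [allele0, allele1, phased]
            row = np.full(len(samples), MISSING_CODE, dtype=np.int8)
            for s_idx, gt in enumerate(rec.genotypes):
                a0, a1 = gt[0], gt[1]
                if a0 < 0 and a1 < 0:
                    continue
                if a0 < 0 or a1 < 0:
                    log.half_calls += 1
                    continue
                alleles = (a_ref, a_alt)
                try:
                    row[s_idx] = encode_pair(alleles[a0], alleles[a1])
                except IndexError:
                    raise ParseError(
                        f"{path}: record {record_no} ({rec.CHROM}:{rec.POS}): "
                        f"GT allele index out of range for sample "
                        f"{samples[s_idx]}"
                    ) from None
            rows.append(row)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(
            f"{path}: malformed VCF record (record {record_no + 1}): {exc}"
        ) from exc

    calls = (
        np.vstack(rows)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeDataset(variants=variants, samples=samples, calls=calls)


def write_vcf(dataset: GenotypeDataset, path: PathLike) -> None:
    """Write a dataset as an uncompressed VCF 4.2 file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = []
        for v in dataset.variants:
            if v.chromosome not in contigs:
                contigs.append(v.chromosome)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples)
            + "\n"
        )
        for i, v in enumerate(dataset.variants):
            gts = []
            ref_code = encode_pair(v.allele_a, v.allele_a)
            het_code = encode_pair(v.allele_a, v.allele_b)
            alt_code = encode_pair(v.allele_b, v.allele_b)
            gt_of = {ref_code: "0/0", het_code: "0/1", alt_code: "1/1",
                     MISSING_CODE: "./."}
            for code in dataset.calls[i]:
                gt = gt_of.get(int(code))
                if gt is None:
                    raise ValidationError(
                        f"call at {v.chromosome}:{v.position} uses alleles "
                        f"outside the variant's {v.allele_a}/{v.allele_b} pair"
                    )
                gts.append(gt)
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.rsid or '.'}\t"
                f"{v.allele_a}\t{v.allele_b}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# PED / MAP


def _read_map(map_path: PathLike) -> list[tuple[str, str, int]]:
    entries = []
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, rsid, _cm, pos = fields
            elif len(fields) == 3:
                chrom, rsid, pos = fields
            else:
                raise ParseError(
                    f"{map_path}:{line_no}: expected 3 or 4 columns, "
                    f"got {len(fields)}"
                )
            try:
                entries.append((chrom, rsid, int(pos)))
            except ValueError:
                raise ParseError(
                    f"{map_path}:{line_no}: non-integer position {pos!r}"
                ) from None
    return entries


_INVENT_ORDER = [Allele.A, Allele.C, Allele.G, Allele.T]


def _second_allele(observed: Allele) -> Allele:
    # deterministic stand-in partner for a monomorphically observed chip
    # variant: lowest base that is neither the observed allele nor its
    # complement (so the invented pair is never strand-ambiguous).
    for cand in _INVENT_ORDER:
        if cand != observed and cand != observed.complement:
            return cand
    raise AssertionError("unreachable")


def read_ped_map(
    ped_path: PathLike,
    map_path: PathLike,
    log: Optional[ParseLog] = None,
) -> GenotypeDataset:
    """Load a PLINK text PED/MAP pair.

    ``0 0`` allele pairs become MISSING; half-missing pairs (``A 0``)
    become MISSING and are counted in the parse log.  Variant allele
    pairs are derived from the observed alleles; when only one allele is
    observed, a deterministic second allele is supplied (and counted) so
    the record stays representable — downstream harmonization excludes
    it if it clashes with the other dataset.
    """
    log = log if log is not None else ParseLog()
    mapping = _read_map(map_path)
    n_var = len(mapping)

    sample_ids: list[str] = []
    raw_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_var:
                raise ParseError(
                    f"{ped_path}:{line_no}: expected {6 + 2 * n_var} columns "
                    f"for {n_var} MAP variants, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            raw_pairs.append(
                [(fields[6 + 2 * k], fields[7 + 2 * k]) for k in range(n_var)]
            )

    n_samples = len(sample_ids)
    calls = np.full((n_var, n_samples), MISSING_CODE, dtype=np.int8)
    variants: list[VariantRecord] = []
    for k, (chrom, rsid, pos) in enumerate(mapping):
        observed: set[str] = set()
        parsed: list[Optional[tuple[str, str]]] = []
        for s in range(n_samples):
            a1, a2 = raw_pairs[s][k]
            miss1, miss2 = a1 == "0", a2 == "0"
            if miss1 and miss2:
                parsed.append(None)
                continue
            if miss1 or miss2:
                log.half_calls += 1
                parsed.append(None)
                continue
            for a in (a1, a2):
                if a not in _VALID_BASES:
                    raise ParseError(
                        f"{ped_path}: sample {sample_ids[s]}, variant {rsid}: "
                        f"invalid allele {a!r}"
                    )
            observed.update((a1, a2))
            parsed.append((a1, a2))
        if len(observed) > 2:
            raise ParseError(
                f"{ped_path}: variant {rsid} shows {len(observed)} alleles "
                f"({sorted(observed)}); only biallelic SNPs are supported"
            )
        if len(observed) == 2:
            a_obs, b_obs = sorted(observed)
            allele_a, allele_b = Allele(a_obs), Allele(b_obs)
        elif len(observed) == 1:
            allele_a = Allele(next(iter(observed)))
            allele_b = _second_allele(allele_a)
            log.monomorphic_variants += 1
        else:  # fully missing column
            allele_a, allele_b = Allele.A, Allele.C
            log.monomorphic_variants += 1
        variants.append(
            VariantRecord(
                chromosome=chrom, position=pos, rsid=rsid,
                allele_a=allele_a, allele_b=allele_b,
            )
        )
        for s, pair in enumerate(parsed):
            if pair is not None:
                calls[k, s] = encode_pair(Allele(pair[0]), Allele(pair[1]))
    return GenotypeDataset(variants=variants, samples=sample_ids, calls=calls)


def write_ped_map(
    dataset: GenotypeDataset,
    ped_path: PathLike,
    map_path: PathLike,
    pedigree: Optional[Sequence[SampleRecord]] = None,
) -> None:
    """Write a dataset as a PLINK text PED/MAP pair.

    The six leading PED columns are filled from *pedigree* when given,
    else with placeholder family/parent fields.
    """
    ped_by_id = {s.sample_id: s for s in pedigree} if pedigree else {}
    with open(map_path, "w") as fh:
        for v in dataset.variants:
            fh.write(f"{v.chromosome}\t{v.rsid or '.'}\t0\t{v.position}\n")
    from .model import decode_code  # local import to avoid cycle noise

    with open(ped_path, "w") as fh:
        for s_idx, sid in enumerate(dataset.samples):
            rec = ped_by_id.get(sid)
            fam = rec.family_id if rec else sid
            father = (rec.father_id or "0") if rec else "0"
            mother = (rec.mother_id or "0") if rec else "0"
            fields = [fam, sid, father, mother, "0", "-9"]
            for v_idx in range(dataset.n_variants):
                pair = decode_code(int(dataset.calls[v_idx, s_idx]))
                if pair is None:
                    fields.extend(("0", "0"))
                else:
                    fields.extend((pair[0].value, pair[1].value))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Genotype-matrix TSV ("GENO" dialect)

_MATRIX_HEADER = ["chrom", "pos", "rsid", "a1", "a2"]


def read_matrix_tsv(path: PathLike) -> GenotypeDataset:
    """Read the genotype-matrix TSV dialect (completed "GENO" calls)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_MATRIX_HEADER)] != _MATRIX_HEADER:
            raise ParseError(
                f"{path}: bad header; expected it to start with "
                f"{' '.join(_MATRIX_HEADER)}"
            )
        samples = header[len(_MATRIX_HEADER):]
        variants: list[VariantRecord] = []
        rows: list[np.ndarray] = []
        for line_no, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if fields == [""]:
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{line_no}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, rsid, a1, a2 = fields[:5]
            try:
                variant = VariantRecord(
                    chromosome=chrom,
                    position=int(pos),
                    rsid=None if rsid in (".", "") else rsid,
                    allele_a=Allele(a1),
                    allele_b=Allele(a2),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: {exc}") from exc
            row = np.full(len(samples), MISSING_CODE, dtype=np.int8)
            for s, cell in enumerate(fields[5:]):
                if cell == "NA":
                    continue
                if (
                    len(cell) != 2
                    or cell[0] not in _VALID_BASES
                    or cell[1] not in _VALID_BASES
                ):
                    raise ParseError(
                        f"{path}:{line_no}: invalid genotype cell {cell!r} "
                        f"for sample {samples[s]}"
                    )
                row[s] = encode_pair(Allele(cell[0]), Allele(cell[1]))
            variants.append(variant)
            rows.append(row)
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeDataset(variants=variants, samples=samples, calls=calls)


def write_matrix_tsv(dataset: GenotypeDataset, path: PathLike) -> None:
    """Write a dataset in the genotype-matrix TSV dialect (lossless)."""
    from .model import decode_code

    with open(path, "w") as fh:
        fh.write("\t".join(_MATRIX_HEADER + list(dataset.samples)) + "\n")
        for i, v in enumerate(dataset.variants):
            cells = []
            for code in dataset.calls[i]:
                pair = decode_code(int(code))
                cells.append("NA" if pair is None else pair[0].value + pair[1].value)
            fh.write(
                "\t".join(
                    [v.chromosome, str(v.position), v.rsid or ".",
                     v.allele_a.value, v.allele_b.value] + cells
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Dosage (MaCH-style)


def read_dosage(path: PathLike, snps_path: PathLike) -> DosageTable:
    """Read MaCH-style dosage text plus its variant-order sidecar.

    The sidecar has one ``rsid<TAB>chromosome`` line per variant, in
    column order.  Dosage rows are ``<sample_id> DOSE d1 d2 ...`` with
    ``NA`` for absent cells.  Values outside [0, 2] are a fatal
    validation error naming the offending variant and sample.
    """
    variant_keys: list[tuple[str, str]] = []
    with open(snps_path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"{snps_path}:{line_no}: expected 'rsid chromosome'"
                )
            variant_keys.append((fields[0], fields[1]))

    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2 + len(variant_keys) or fields[1] != "DOSE":
                raise ParseError(
                    f"{path}:{line_no}: expected '<id> DOSE' followed by "
                    f"{len(variant_keys)} values"
                )
            sid = fields[0]
            samples.append(sid)
            row = np.full(len(variant_keys), np.nan)
            for k, cell in enumerate(fields[2:]):
                if cell == "NA":
                    continue
                try:
                    value = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{line_no}: non-numeric dosage {cell!r}"
                    ) from None
                if not 0.0 <= value <= 2.0:
                    rsid, chrom = variant_keys[k]
                    raise ValidationError(
                        f"dosage {value} out of [0, 2] at variant {rsid} "
                        f"(chr{chrom}), sample {sid}"
                    )
                row[k] = value
            rows.append(row)
    values = (
        np.vstack(rows).T
        if rows
        else np.empty((len(variant_keys), 0))
    )
    return DosageTable(variant_keys=variant_keys, samples=samples, values=values)


def write_dosage(table: DosageTable, path: PathLike, snps_path: PathLike) -> None:
    with open(snps_path, "w") as fh:
        for rsid, chrom in table.variant_keys:
            fh.write(f"{rsid}\t{chrom}\n")
    with open(path, "w") as fh:
        for s, sid in enumerate(table.samples):
            cells = [
                "NA" if np.isnan(v) else f"{v:.3f}"
                for v in table.values[:, s]
            ]
            fh.write(f"{sid} DOSE " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Pedigree TSV


def read_pedigree(path: PathLike) -> list[SampleRecord]:
    """Read the pedigree TSV; parent references are validated."""
    records: list[SampleRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if line_no == 1 and fields[0] == "family_id":
                continue
            if len(fields) != 5:
                raise ParseError(
                    f"{path}:{line_no}: expected 5 columns "
                    "(family_id sample_id father_id mother_id sequenced)"
                )
            fam, sid, father, mother, seq = fields
            if seq not in ("0", "1"):
                raise ParseError(
                    f"{path}:{line_no}: sequenced flag must be 0 or 1"
                )
            try:
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        family_id=fam,
                        father_id=None if father == "0" else father,
                        mother_id=None if mother == "0" else mother,
                        sequenced=seq == "1",
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{line_no}: {exc}") from exc
    try:
        validate_pedigree(records)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return records


def write_pedigree(samples: Sequence[SampleRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tsample_id\tfather_id\tmother_id\tsequenced\n")
        for s in samples:
            fh.write(
                f"{s.family_id}\t{s.sample_id}\t{s.father_id or '0'}\t"
                f"{s.mother_id or '0'}\t{int(s.sequenced)}\n"
            )
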