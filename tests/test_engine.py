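"""Engine semantics: classification, stratified accumulation, audits.

The accumulation oracle here is a deliberately naive per-cell enumerator
written from the comparison rules directly (sets and loops, no numpy),
kept independent of the engine implementation it checks.
"""

import numpy as np
import pytest

from genoconcord import (
    Allele,
    ComparisonConfig,
    ComparisonOutcome,
    DiscrepancyType,
    GenotypeCall,
    GenotypeDataset,
    HarmonizedPair,
    ProcessClass,
    SampleRecord,
    VariantRecord,
    accumulate,
    call_rate,
    classify_discrepancy,
    classify_process,
    compare_call,
    detect_outliers,
    dosage_audit,
    remove_samples,
    select_high_call_rate,
    zero_discrepancy_fraction,
)
from genoconcord.errors import ValidationError
from genoconcord.model import MISSING, MISSING_CODE, DosageTable, encode_pair

from conftest import make_dataset, var

AC = GenotypeCall.from_strings("A", "C")
AA = GenotypeCall.from_strings("A", "A")
CC = GenotypeCall.from_strings("C", "C")


# ---------------------------------------------------------------------------
# scalar operations


def test_classify_process_covers_all_four_classes():
    seq = SampleRecord("S", "F", sequenced=True)
    unseq = SampleRecord("U", "F", sequenced=False)
    assert classify_process(seq, AA, True) is ProcessClass.SEQUENCED
    assert classify_process(seq, MISSING, True) is ProcessClass.IMPUTED
    assert classify_process(unseq, MISSING, True) is ProcessClass.INFERRED_FAM_SEQ
    assert classify_process(unseq, MISSING, False) is ProcessClass.INFERRED_FAM_NOSEQ


def test_compare_call_missing_never_discrepant():
    assert compare_call(AC, GenotypeCall.from_strings("C", "A")) \
        is ComparisonOutcome.CONCORDANT
    assert compare_call(AA, AC) is ComparisonOutcome.DISCREPANT
    assert compare_call(AA, MISSING) is ComparisonOutcome.NOT_COMPARED
    assert compare_call(MISSING, MISSING) is ComparisonOutcome.NOT_COMPARED


def test_classify_discrepancy_patterns():
    assert classify_discrepancy(AA, AC) is DiscrepancyType.HOM_TO_HET
    assert classify_discrepancy(AC, CC) is DiscrepancyType.HET_TO_HOM
    assert classify_discrepancy(AA, CC) is DiscrepancyType.HOM_TO_OPP_HOM
    with pytest.raises(ValueError):
        classify_discrepancy(AA, AA)


def test_call_rate_fractions_and_empty_subset():
    ds = make_dataset(
        [var("1", 100, "rs1", "A", "C")],
        ["S1", "S2", "S3", "S4", "S5"],
        [["AC", "AA", "NA", "CC", "AC"]],
    )
    assert call_rate(ds, 0) == pytest.approx(0.8)
    assert call_rate(ds, 0, ["S1", "S2"]) == 1.0
    with pytest.raises(ValidationError):
        call_rate(ds, 0, [])


def test_select_high_call_rate_inclusive_boundary():
    # 100 GWAS samples, 50 sequenced; variant A: exactly 98%/98%; variant
    # B: 99% GWAS but 90% (45/50) sequencing -> excluded
    n, ns = 100, 50
    gwas_cells = [
        ["AC"] * (n - 2) + ["NA"] * 2,  # 98/100
        ["AC"] * (n - 1) + ["NA"],      # 99/100
    ]
    seq_cells = [
        ["AC"] * (ns - 1) + ["NA"],     # 49/50 = 98%
        ["AC"] * (ns - 5) + ["NA"] * 5,  # 45/50 = 90%
    ]
    variants = [var("1", 100, "rsA", "A", "C"), var("1", 200, "rsB", "A", "C")]
    gwas = make_dataset(variants, [f"G{i}" for i in range(n)], gwas_cells)
    seq = make_dataset(variants, [f"G{i}" for i in range(ns)], seq_cells)
    pairs = [
        HarmonizedPair(("rsA", "1"), 0, 0, False),
        HarmonizedPair(("rsB", "1"), 1, 1, False),
    ]
    kept = select_high_call_rate(pairs, gwas, seq, ComparisonConfig())
    assert [p.variant_key[0] for p in kept] == ["rsA"]


def test_zero_discrepancy_fraction():
    assert zero_discrepancy_fraction({"a": 0, "b": 0, "c": 0, "d": 1}) == 0.75
    assert zero_discrepancy_fraction({"a": 0}) == 1.0
    with pytest.raises(ValidationError):
        zero_discrepancy_fraction({})


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"X": 11576, "Y": 1880, "Z": 1500}, ["X"]),
        ({"X": 7, "Y": 7, "Z": 7}, []),
        ({"X": 100, "Y": 10}, []),  # large gap but below the absolute floor
    ],
)
def test_detect_outliers_gap_and_floor_rule(counts, expected):
    assert detect_outliers(counts, ComparisonConfig()) == expected


def test_remove_samples_drops_everywhere_and_validates():
    ds = make_dataset(
        [var("1", 100, "rs1", "A", "C")], ["S1", "S2", "S3"], [["AC", "AA", "CC"]]
    )
    (smaller,) = remove_samples([ds], {"S2"})
    assert smaller.samples == ["S1", "S3"]
    (same,) = remove_samples([ds], set())
    assert same.equals(ds)
    with pytest.raises(ValidationError):
        remove_samples([ds], {"nobody"})


# ---------------------------------------------------------------------------
# accumulate: small direct case


def _tiny_setup():
    variants = [var("1", 100, "rs1", "A", "C"), var("1", 200, "rs2", "G", "T")]
    samples = [
        SampleRecord("S1", "F1", sequenced=True),
        SampleRecord("S2", "F2", sequenced=False),
    ]
    gwas = make_dataset(variants, ["S1", "S2"], [["AA", "AC"], ["GT", "GG"]])
    geno = make_dataset(variants, ["S1", "S2"], [["AC", "AC"], ["GT", "GG"]])
    seq = make_dataset(variants, ["S1"], [["NA"], ["GT"]])
    pairs = [
        HarmonizedPair(("rs1", "1"), 0, 0, False),
        HarmonizedPair(("rs2", "1"), 1, 1, False),
    ]
    return pairs, gwas, geno, seq, samples


def test_accumulate_counts_single_injected_discrepancy():
    pairs, gwas, geno, seq, samples = _tiny_setup()
    result = accumulate(pairs, gwas, geno, seq, samples)
    assert result.total_discrepant == 1
    assert result.per_individual == {"S1": 1, "S2": 0}
    fams = {f.family_id: f for f in result.family_summaries}
    assert fams["F1"].d_all == 1 and fams["F2"].d_all == 0
    # S1's rs1 geno call was an imputed fill (no raw read)
    imp = result.process_summary("Imputation")
    assert imp.discrepant == 1 and imp.genotypes == 1 and imp.subjects == 1
    assert result.type_tallies[DiscrepancyType.HOM_TO_HET] == 1
    # partition: every cell classified exactly once
    assert result.outcomes.size == len(pairs) * 2
    assert result.total_compared + int(
        np.count_nonzero(result.outcomes == ComparisonOutcome.NOT_COMPARED)
    ) == result.outcomes.size


def test_accumulate_rejects_sample_missing_from_pedigree():
    pairs, gwas, geno, seq, samples = _tiny_setup()
    with pytest.raises(ValidationError, match="S2"):
        accumulate(pairs, gwas, geno, seq, samples[:1])


# ---------------------------------------------------------------------------
# accumulate vs independent brute-force enumeration


def brute_force_totals(pairs, gwas, geno, seq, samples):
    """Naive per-cell enumeration of every statistic the engine reports."""
    by_id = {s.sample_id: s for s in samples}
    fam_seq = {s.family_id for s in samples if s.sequenced}
    seq_keys = {}
    for i, v in enumerate(seq.variants):
        seq_keys[(v.rsid, v.chrom_norm)] = i
    per_ind = {s: 0 for s in gwas.samples}
    per_var = {}
    per_proc = {}
    fam = {}
    for p in pairs:
        per_var[p.variant_key] = 0
        for s_idx, sid in enumerate(gwas.samples):
            rec = by_id[sid]
            g = gwas.call(p.left_index, sid)
            n = geno.call(p.right_index, sid)
            if rec.sequenced:
                vi = seq_keys.get(p.variant_key)
                read_present = (
                    vi is not None
                    and sid in seq.samples
                    and not seq.call(vi, sid).is_missing
                )
                proc = "SEQUENCED" if read_present else "IMPUTED"
            else:
                proc = (
                    "INFERRED_FAM_SEQ"
                    if rec.family_id in fam_seq
                    else "INFERRED_FAM_NOSEQ"
                )
            entry = per_proc.setdefault(proc, {"n": 0, "d": 0, "subj": set()})
            if g.is_missing or n.is_missing:
                continue
            entry["n"] += 1
            entry["subj"].add(sid)
            if g.alleles != n.alleles:
                entry["d"] += 1
                per_ind[sid] += 1
                per_var[p.variant_key] += 1
    for s in samples:
        if s.sample_id not in per_ind:
            continue
        f = fam.setdefault(s.family_id, {"d_seq": 0, "d_nonseq": 0})
        key = "d_seq" if s.sequenced else "d_nonseq"
        f[key] += per_ind[s.sample_id]
    return per_ind, per_var, per_proc, fam


def _random_instance(rng):
    n_var = int(rng.integers(1, 11))
    n_samp = int(rng.integers(2, 11))
    variants = [var("1", 100 + i, f"rs{i}", "A", "C") for i in range(n_var)]
    samples = []
    for k in range(n_samp):
        fam = f"F{k % 3}"
        samples.append(
            SampleRecord(f"S{k}", fam, sequenced=bool(rng.integers(2)))
        )
    ids = [s.sample_id for s in samples]
    codes = [
        encode_pair(Allele.A, Allele.A),
        encode_pair(Allele.A, Allele.C),
        encode_pair(Allele.C, Allele.C),
        MISSING_CODE,
    ]

    def matrix(cols):
        return np.array(
            rng.choice(codes, size=(n_var, len(cols))), dtype=np.int8
        )

    gwas = GenotypeDataset(variants=variants, samples=ids, calls=matrix(ids))
    geno = GenotypeDataset(variants=variants, samples=ids, calls=matrix(ids))
    seq_ids = [s.sample_id for s in samples if s.sequenced]
    seq = GenotypeDataset(
        variants=variants, samples=seq_ids, calls=matrix(seq_ids)
    )
    pairs = [HarmonizedPair((f"rs{i}", "1"), i, i, False) for i in range(n_var)]
    return pairs, gwas, geno, seq, samples


def test_accumulate_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        pairs, gwas, geno, seq, samples = _random_instance(rng)
        result = accumulate(pairs, gwas, geno, seq, samples)
        per_ind, per_var, per_proc, fam = brute_force_totals(
            pairs, gwas, geno, seq, samples
        )
        assert result.per_individual == per_ind
        assert result.per_variant == per_var
        for s in result.process_summaries:
            key = {
                "Sequencing": "SEQUENCED",
                "Imputation": "IMPUTED",
                "Inference-families-with-sequence": "INFERRED_FAM_SEQ",
                "Inference-families-without-sequence": "INFERRED_FAM_NOSEQ",
            }[s.process]
            expect = per_proc.get(key, {"n": 0, "d": 0, "subj": set()})
            assert (s.genotypes, s.discrepant, s.subjects) == (
                expect["n"], expect["d"], len(expect["subj"])
            )
        for f in result.family_summaries:
            expect = fam.get(f.family_id, {"d_seq": 0, "d_nonseq": 0})
            assert (f.d_seq, f.d_nonseq) == (expect["d_seq"], expect["d_nonseq"])
        # additivity across stratifications
        total = result.total_discrepant
        assert sum(f.d_all for f in result.family_summaries) == total
        assert sum(s.discrepant for s in result.process_summaries) == total
        assert sum(result.per_variant.values()) == total


# ---------------------------------------------------------------------------
# dosage audit


def _audit_setup():
    variants = [var("1", 100, "rs1", "A", "C")]
    geno = make_dataset(variants, ["S1", "S2", "S3"], [["AC", "NA", "AA"]])
    table = DosageTable(
        variant_keys=[("rs1", "1")],
        samples=["S1", "S2", "S3"],
        values=np.array([[1.0, 0.999, 2.0]]),
    )
    return geno, table


def test_dosage_audit_tallies_and_violations():
    geno, table = _audit_setup()
    report = dosage_audit(geno, table, ComparisonConfig())
    # S1: integral+present OK; S2: nonintegral+blank OK; S3 call is A/A with
    # dosage 2.0 -> integral+present
    assert report.n_violations == 0
    assert report.integral_present == 2
    assert report.nonintegral_blank == 1

    bad = DosageTable(
        variant_keys=[("rs1", "1")],
        samples=["S1", "S2", "S3"],
        values=np.array([[0.999, 0.999, 2.0]]),
    )
    report = dosage_audit(geno, bad, ComparisonConfig())
    assert report.n_violations == 1
    assert report.violations[0][:3] == ("rs1", "1", "S1")


def test_dosage_integral_blank_is_not_a_violation():
    variants = [var("1", 100, "rs1", "A", "C")]
    geno = make_dataset(variants, ["S1"], [["NA"]])
    table = DosageTable(
        variant_keys=[("rs1", "1")], samples=["S1"], values=np.array([[2.0]])
    )
    report = dosage_audit(geno, table, ComparisonConfig())
    assert report.n_violations == 0 and report.integral_blank == 1
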