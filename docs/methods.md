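# Methods

## Comparison model

The unit of comparison is a (variant, individual) cell holding two
genotype calls oriented to the same strand: the GWAS-chip call and the
completed-matrix ("GENO") call. Calls are unordered diploid allele
pairs over {A, C, G, T} or missing; half-calls are normalised to missing
at parse time (and counted), because the comparison rule only
distinguishes "called in both datasets" from everything else. A cell is

* **not compared** if either call is missing — platforms differ in call
  rate, and missingness must not masquerade as disagreement;
* **concordant** if the unordered pairs are equal;
* **discrepant** otherwise. Discrepant cells are further typed by
  zygosity pattern: hom→het (chip homozygote, completed heterozygote),
  het→hom, or hom→opposite-hom; two distinct heterozygotes are
  impossible at a biallelic SNP and are asserted against.

### Harmonization

Variants are matched on rsID + chromosome (labels normalised by
stripping a `chr` prefix), never on position: genome-build drift between
a chip manifest and a sequencing reference makes position disagreement
routine, so it is counted but not excluded. rsIDs must occur exactly
once in *each* dataset; duplicates are dropped entirely. Matched allele
pairs are classified SAME, FLIPPED (each the other's Watson–Crick
complement, e.g. A/C vs T/G), AMBIGUOUS, or INCOMPATIBLE. A/T and C/G
SNPs are ambiguous — their two strand representations are
indistinguishable — and are discarded unconditionally, even when the
letters agree; no frequency-based rescue is attempted. The
sequence-side dataset is complemented onto the chip strand (direction is
arbitrary; fixed for determinism), and orienting twice restores the
original, which is property-tested.

### Process classification

For a sequenced individual, the completed call at a cell is labelled
**sequenced** when the raw-read VCF has a call there and **imputed**
when it does not (the completed matrix filled a gap). Unsequenced
individuals' cells are **inferred**, stratified into
families-with-sequence vs families-without-sequence. Per-process
summaries count compared calls, discrepancies, and subjects
(individuals contributing ≥ 1 compared call of that process); the
pooled Inference row sums the two strata. All accumulation is in exact
integers; rounding happens only at rendering, decimal half-up (binary
`round()` would turn 5287/20 = 264.35 into 264.3; the tables print
264.4), with D/N to 1 decimal and percentages to 2.

### SNP-set filtering and outliers

The *high-call-rate* subset keeps variants with call rate ≥ 0.98
(inclusive) on both platforms: the chip rate over all retained study
individuals, the sequencing rate over sequenced individuals only, using
raw pre-imputation reads. A variant absent from the raw reads cannot
demonstrate the required sequencing call rate and is excluded.

Outlier screening formalises "one individual with an extreme count and
a large gap to the rest": scanning counts in descending order, an
individual is flagged while their count exceeds `outlier_gap_factor`
(default 3.0) times the next-highest count *and* is at least
`outlier_min_count` (default 5000). Flagged individuals are removed
from every downstream universe. Outlier removal runs before the
per-SNP call-rate filter (the order is a config knob recorded in the
run manifest; with typical missingness the two orderings differ
negligibly, but removal-first keeps call-rate denominators honest).

### Dosage audit

Imputation pipelines blank fills they are not confident in; those cells
carry non-integral dosages (e.g. 0.001, 0.999) while emitted calls have
dosages exactly 0, 1 or 2. The audit flags any cell whose dosage is
further than `dosage_integrality_tolerance` (default 1e-6) from every
integer *and* whose completed call is present, and tallies all audited
cells by (integral?, present?).

## Synthetic cohort generator

The generator emulates the study design the evaluation was built for: a
multi-generation family cohort (default 20 families of 25–70 members,
≈ 950 individuals) in which 4 families have no sequenced members and
about half of each remaining family is sequenced.

* **Pedigrees** grow breadth-first from a founder couple: couples bear
  1–4 children; children below the final generation (default 4
  generations) marry an in-migrating founder spouse with probability
  0.7; extra children top families up to their target size. Samples are
  listed parents-before-children, so gene dropping is a single pass.
* **Truth** comes from gene dropping: founder minor-allele counts are
  Binomial(2, f) with f ~ Uniform(0.05, 0.5) per variant (common-variant
  range; rare variants would need far larger cohorts for stable rate
  estimates at this scale), and each child receives one uniformly
  chosen allele from each parent. Mendelian consistency of every cell
  is verified exhaustively in the tests.
* **Variants**: default 5,000 (thousands rather than the millions of a
  real study, so end-to-end runs take seconds; all statistics scale per
  compared call). 15% are assigned A/T or C/G pairs so the ambiguity
  filter has real work; half the variants are on the chip; 30% of
  non-ambiguous chip variants are reported on the opposite strand.
* **Chip channel**: per-call missingness 0.5%, per-call error 0.03%
  (the wrong genotype uniform among the two alternatives). These two
  rates reproduce the observed chip-vs-read disagreement level.
* **Sequence channel**: per-call read missingness 0.2%, so ≈ 0.2% of a
  sequenced individual's completed calls are imputed fills.
* **Imputation channel**: a fraction `imputation_error_rate` (default
  0.25) of imputed fills is wrong, and `het_bias` (default 0.986) *of
  all wrong fills* are homozygous-truth cells emitted heterozygous —
  the signature failure of likelihood-based pedigree imputation, where
  a heterozygote is compatible with every relative configuration. The
  channel realises this by splitting the error budget
  R·(imputed cells): a het_bias share falls on homozygous-truth cells
  (always miscalled het), the residual on heterozygous-truth cells
  (miscalled as a uniform homozygote). Hom→opposite-hom double
  miscalls get zero mass: they would require two independent allele
  errors in one fill and are vanishingly rare in the emulated process.
* **Inference channel**: inferred calls are wrong with probability
  `inference_error_rate_famseq` (default 0.0007), multiplied by
  `inference_noseq_multiplier` (default 2.0) in families with no
  sequenced members; the wrong genotype is uniform among the two
  alternatives.
* **Blanking and dosages**: 2% of fills are blanked (uniformly at
  random, independent of error status — real pipelines blank
  *suspected* errors, which would couple blanking to the error process;
  the independent version keeps the injected rates identifiable).
  Blanked cells carry non-integral dosages (integer ± U(0.001, 0.4));
  present calls carry their exact allele count.
* **Sample swaps**: a configured (target, donor) pair replaces the
  target's chip column with the donor's, one-way. A reciprocal swap of
  two in-cohort members would create two near-equal extreme counts that
  a gap-based outlier rule cannot separate; the phenomenon modelled is
  a single corrupted specimen.
* A **ground-truth ledger** records every cell's true genotype, process
  label and injection flag; label recovery by the engine is exact
  (100%) by construction and asserted on cohort-scale runs.

One global seed feeds a hierarchy of named child streams (pedigree,
gene drop, chip selection, each error channel, dosage noise), so
sub-processes are independently reproducible and scenario files are
byte-identical across runs.

### What the generator does not emulate

No linkage disequilibrium or haplotype structure (variants are
independent), no phasing, no admixture or Hardy–Weinberg departure, no
per-platform chip heterogeneity (one chip missingness rate), and no
actual imputation software — the channels model the *distribution* of
errors, not their mechanism. Passing recovery tests therefore shows the
evaluation pipeline measures injected error structure correctly, not
that any particular imputation tool has these error rates.

## Numerical and design choices

* Genotype calls are stored as signed-byte unordered-pair codes
  (allele indices A=0…T=3, pair (i ≤ j) → 4i+j, missing −1); strand
  complement is index reversal, so flips and comparisons are table
  lookups over numpy matrices.
* Rate-recovery experiments (tests and the acceptance script) set the
  chip error rate to zero: with chip noise g, the per-process
  chip-vs-completed discrepancy rate estimates the composite
  i + g(1−i) rather than the injected channel rate i, which matters
  precisely at the scale (3 binomial SE on ~10⁶ calls) those
  experiments resolve.
* Recovery tolerances are 3 binomial standard errors at the realised
  call counts (≥ 10,000 compared calls per process class in the
  recovery scenario; the imputation workload is densified to
  `seq_missing_rate = 0.015` there to reach that count).
* The outlier-detection scenario uses 36,000 variants in a smaller
  8-family cohort so a swapped individual's expected discrepancy count
  (≈ 0.4 × compared chip calls) clears the 5,000 absolute floor with
  margin while the clean run's maximum stays two orders of magnitude
  below it.
* Ties in outlier scanning and table sorting break on identifiers, so
  every report is deterministic.
* Degenerate inputs: empty harmonization results are permitted
  everywhere; call rate over an empty sample subset, zero-discrepancy
  fraction of an empty variant set, and removal of unknown samples are
  errors; monomorphically observed chip variants get a deterministic
  invented partner allele (never forming an ambiguous pair) and are
  counted — harmonization keeps them when compatible and drops them
  conservatively otherwise.

## Known limitations

* PED/MAP cannot represent a variant's unobserved allele, so allele
  pairs are reconstructed from data; fully missing or monomorphic chip
  columns may be excluded from comparison where an in-memory dataset
  would be retained.
* The dosage text format carries 3 decimals; round-tripping preserves
  integrality status but not full float precision.
* BCF/binary PLINK, genotype likelihoods and phased semantics are out
  of scope; phase separators are accepted and ignored.
* Chance-corrected concordance measures (e.g. IQS) are not computed;
  the statistics here are raw discrepancy rates.
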