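# Methods

## The simulation model

A *reference set* is a collection of mature small-RNA sequences with
genomic coordinates: known miRNAs (17–24 nt), novel miRNAs (17–24 nt,
i.e. curated sequences absent from the standard annotation) and known
piRNAs (25–31 nt). A simulation draws a *molecule set* from these
references and emits `total_reads` sequencing reads in four classes:

* **known miRNA / novel miRNA / known piRNA** — reads carrying an
  unaltered reference sequence;
* **other (decoy)** — reads carrying a sequence derived from a real
  miRNA or piRNA by substituting at least 2 nt inside the seed region,
  the xseed region, or both. A correct pipeline must reject these, so
  they serve as true negatives when scoring. The 2-nt minimum is chosen
  because common spliced/short-read aligners tolerate up to 2 mismatches;
  a 1-nt decoy would still align and would not discriminate pipelines.

The seed region defaults to mature positions 2–8 (1-based inclusive),
the standard target-recognition window; it is a parameter
(`seed_range`) everywhere it is used, since authors of reference
pipelines do not all agree on the exact window. The xseed region is
everything outside the seed.

### Read allocation and expression

The read budget is split in this order, every split using
largest-remainder (Hamilton) apportionment so integer budgets sum
exactly:

1. across the four classes by the configured percentages
   (`pct_known_mirna`, `pct_novel_mirna`, `pct_pirna`; the decoy share is
   the closure to 100%);
2. within a class, across chromosomes proportionally to the number of
   class references on each chromosome;
3. within a chromosome, molecules are sampled without replacement (decoy
   *sources* with replacement — decoys are derived copies, not the
   references themselves) and each receives an expression count drawn
   from the configured distribution, floored at `min_depth`
   (decoys floored at 1): Poisson(mean) draws are used as-is,
   gamma(shape, scale) draws are rounded half-up to integers before
   flooring. Draws are clamped to the remaining budget; a terminal
   remainder smaller than the floor is folded into the last emitted
   molecule, so totals are exact and the floor is never violated.

Consequences asserted by the test suite: the FASTQ has exactly
`total_reads` records; per-class read totals equal the
largest-remainder-rounded targets; every non-decoy molecule has count ≥
`min_depth`; identical configuration ⇒ byte-identical outputs.

### Read assembly and outputs

Each read is the mature (possibly altered or reverse-complemented)
sequence followed by the 3′ adapter and then primer sequence, repeated
as filler if needed and truncated to `read_length` (default 75 nt, the
common single-end small-RNA read length). Defaults are the Illumina
TruSeq small-RNA 3′ adapter and its RT primer; both are overridable, and
with both empty the filler degenerates to repeated `a`. The quality
string is a constant Phred+33 symbol (default `I`, Q40) — the simulator
deliberately has **no sequencing-error model**; decoy alterations are
the only deviation from the references. CIGAR records the mature portion
as a full match (`22M` etc.); adapter padding is not represented.

FASTQ headers are `@<molecule_name>_<read_index>` with the index counting
1..expression_count per molecule. The ground-truth CSV columns, in order:
`molecule_name, rna_class, sequence, chrom, start, end, strand,
expression_count, cigar, source_id, alteration_mode` (`source_id` and a
non-`none` `alteration_mode` only for decoys).

### Reverse-complement mode

`rc_mode=True` reproduces the benchmark design that probes whether a
pipeline recognises reverse-complemented known miRNAs: every reference
contributes the reverse complement of its mature sequence at a fixed
depth of `min_depth` reads (class percentages are ignored). With 887
references at depth 10 this yields exactly 8,870 reads.

## Annotation logic

* **Triage** is by insert length only: 17–24 nt → miRNA track, 25–31 nt
  → piRNA track, ≥ 32 nt rejected. Reads of ≤ 16 nt are also rejected:
  they are shorter than any mature miRNA and cannot enter either track.
* **Quality filter**: drop a read iff *strictly more than* 10% of bases
  have Phred < 20 (both thresholds configurable). Exactly 10% is kept.
* **Reverse-complement re-annotation** replaces an online BLAST lookup
  with a local exact-match index of known mature sequences, for
  determinism and offline testability. A novel candidate matching a
  known sequence forward is relabelled known directly; otherwise its
  reverse complement must match *and* the genomic interval must be equal
  (chromosome, start, end; strand deliberately ignored — an RC read maps
  to the opposite strand of its true miRNA). Counts merge into the known
  entry; total counts are conserved.
* **Clustering** merges novel detections with identical seeds, xseed
  Hamming distance ≤ 2 (equal length required — Hamming is undefined
  otherwise, and a length change is more than a 2-nt alteration), and
  start positions ≤ 2 nt apart on the same chromosome and strand.
  "Genomic position" is interpreted as the start coordinate. Merging is
  the transitive closure over qualifying pairs; the cluster
  representative is the highest-count member (ties: smallest start, then
  lexicographic sequence). Re-clustering merged output is a no-op.
* **Functional naming** orders clusters by descending merged count
  (ties: locus, then sequence) so names are independent of input row
  order. A cluster sharing a known miRNA's seed at a *different* locus
  becomes `<known>_n` (paralogue); at the *same* locus it is the known
  miRNA itself. A cluster sharing the seed of an earlier unique novel
  becomes `<novel>_n`. Paralogue indices are global across the input,
  not per sample.
* **Deduplication**: rows with the same mature sequence at several loci
  are one molecule reported multiple times with equal counts; they
  collapse to one row listing all loci, keeping the count once. Unequal
  counts for the same sequence are inconsistent input: the maximum is
  kept and a warning logged.
* **Final renaming**: unique novels take an identifier from a
  user-supplied sequence→id table when present (replacing an online
  homology search), otherwise sequential `novel-mir-k` names; every
  final novel name carries a `*` suffix marking it putative. Paralogue
  labels (`hsa-mir-x_n`) are kept as assigned — they are statements
  about a known anchor, not new names.

## Scoring

Reads (molecules weighted by expression count) score as: TP — correct
class-1..3 assignment; FP — wrong assignment *into* a class 1..3; FN —
real molecule rejected to class 4; TN — decoy rejected. A read predicted
as the wrong non-rejection class is FP to the predicted class only (FN
is reserved for rejection). The four cells partition the scored reads,
so accuracy = (TP+TN)/total is well defined. F1 uses the convention
F1 = 0 when precision + recall = 0. Per-class tables restrict the same
definitions to one class (TN, which involves no class, is shared);
overall metrics pool the cells (micro-averaging). A truth id with no
prediction is scored as rejected, matching how pipelines silently drop
reads; a prediction id absent from the truth is an error.

Report percentages compared against external validation are *truncated*
(not rounded) to two decimals — `(1 − 9/29)·100 = 68.9655…` is reported
as 68.96 — matching the convention of the published tables these numbers
are compared against; full-precision values are a one-line computation
away via the untruncated formula.

## The fixture generator

`make_fixture_records` fabricates uniform-random unique mature sequences
(miRNA/novel 17–24 nt, piRNA 25–31 nt) at non-overlapping loci spread
round-robin across `n_chromosomes` chromosomes, with random strands,
deterministic under its seed. It emulates the *shape* of real reference
sets — class-specific length bands, coordinates, uniqueness — but not
their composition biases: no sequence-composition realism (GC content,
seed-family structure), no overlapping or clustered loci, no isomiRs,
and no chromosome-size effects. Tests passing on fixtures therefore
demonstrate the correctness of the bookkeeping, the alteration and
clustering rules, and the metric arithmetic — not performance on real
genomes.

## Problem sizes and numerical choices

The test suite simulates 4,000–20,000 reads over 18–110 reference
molecules, checks 10,000 decoys, 1,000 random clustering tables (≤ 10
detections each) and 1,000 random confusion fixtures; the
reverse-complement benchmark runs at its natural size (887 × 10). These
sizes give exact combinatorial checks and tight Monte-Carlo bounds
(Poisson mean within 3 standard errors at n = 10,000) while keeping the
full suite under a few seconds.

Known limitations: no sequencing-error or quality-degradation model, no
isomiR or precursor/hairpin evaluation, single-end reads only, no
differential-expression step, and the annotation stage assumes exact
sequence matches (it sits downstream of an aligner, which it does not
replace).
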