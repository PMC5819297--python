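# Methods

`chromoscan` implements, as a tested and reusable pipeline, an
in-silico workflow for characterizing the DNA content of mouse
chromocenters (pericentromeric constitutive heterochromatin) from short
Illumina reads: read cleaning, best-hit classification of reads against
a repeat consensus library, per-nucleotide coverage profiling along
transposable-element consensuses, large tandem-repeat (TR) array
detection in contigs, and a contig screen for satellite + ERV
co-occurrence.  Every stage is exercised on seeded synthetic data with
known ground truth; nothing here requires downloads of reference
repeats, SRA runs, or genome assemblies.

## Read cleaning

Reads are cleaned with sliding-window quality trimming (window 4 bp,
mean phred threshold 25), a minimum-length filter (30 bp), and an
optional exact-substring adapter drop (the default adapter set is empty;
synthetic reads carry no adapters).  The window scan runs 5'→3' and the
read is cut at the first window whose mean quality falls below the
threshold — except that leading bases of that window whose individual
quality still meets the threshold are retained.  This per-base extension
is the semantics of the widely used SLIDINGWINDOW trimmers and is what
the module's hand-enumerated oracle encodes: a 37-bp read with quality
40 everywhere except positions 31–34 (quality 10) is trimmed to exactly
30 bases, because the first failing window starts at position 30 but its
first base still scores 40.  A cut at the bare window start would keep
29 bases and wrongly drop the read.

Percent denominators downstream use all cleaned reads; paired-end mates
are pooled and counted as single reads.

## Classification model

Each cleaned read is assigned to at most one repeat family — the family
with the single best local alignment across the library.  The aligner is
an affine-gap Smith–Waterman (match +2, mismatch −3, gap open −5, gap
extend −2; a gap of length L costs −5 −2(L−1)), numba-compiled, with two
acceptance floors: score ≥ 40 and ≥ 20 alignment columns.  Both read
strands are tried.

Candidate placements come from an 11-mer seed index over the library.
Seed matches are grouped into diagonal clusters (tolerance 5 bp, at most
8 clusters per reference ranked by seed support) and each cluster is
aligned in a padded window.  The seed stage is lossless for any
alignment containing one exact 11-mer.  Reads whose seeded candidates
produce no qualifying alignment are rescanned exhaustively (score-only
dynamic programming against every reference), so a read is only reported
unassigned after a full scan; at 5 % copy divergence a few percent of
37-bp reads lack a clean 11-mer, and without the rescan the recovered
satellite fractions would be biased low by several points.  An
`exhaustive` flag disables the seed stage entirely.

Tandem (satellite) consensuses are searched in duplicated form (monomer
× 2), which contains every junction-spanning k-mer of the circular
monomer as long as reads are shorter than the monomer; reported
coordinates are reduced modulo the monomer length (the end coordinate
may exceed the monomer length to indicate wrap-around, keeping start <
end).  The telomeric reference is the 6-bp unit TTAGGG expanded to 20
units, since the unit alone is shorter than a read.

Ties across families at the best score are broken by repeat-class
priority (TR > LINE > SINE > ERV1 > ERV2 > ERV3 > DNA > OTHER), then by
name, and are always surfaced via an `ambiguous` flag, never hidden.
Composition percentages are count/total-cleaned-reads, so the
"All repeats" roll-up directly measures the annotated fraction of the
dataset.  Roll-ups are reported at class level with ERV shown three ways
(total, per class, intracisternal-A-particle separately) and a
per-consensus internal-vs-LTR table.

## Coverage profiles and enrichment segments

A profile counts aligned read bases per consensus position (one
increment per covered position per read).  Profiles are made comparable
across datasets by reads-per-million scaling (`per / n_reads_total`,
default per = 10⁶); normalizing twice, or normalizing a profile from an
empty dataset, is an error.  Profiling uses seeded alignments only by
default: at realistic error rates this thins coverage uniformly by a few
percent, which cannot move fold-based calls; a flag restores the
exhaustive rescan.

Enrichment calling is entirely this package's design — coverage
profiles are usually judged by eye, and turning "the peaks concentrate
here" into a reproducible call needs explicit rules: the profile is
smoothed with a
centered 101-bp moving average, positions where the smoothed value is at
least 3× the profile median are marked, marked runs closer than the
smoothing window are merged, and runs of at least 200 bp are reported
with their mean fold enrichment.  All three knobs are exposed.  A
profile with median zero yields no calls — segment calling needs a
defined baseline, so sparse profiles (most positions uncovered) are out
of scope for this caller.  Calls are invariant under global scaling and
under profile reversal.

With the default LINE truncation model (below), the planted 2.0-kb
3'-terminal window is recovered as a single segment of ≈ 1.9 kb: the
smoothing ramp erodes each boundary by roughly half a window, an
acceptable bias at the 101-bp default.

## Tandem arrays and the large-TR definition

Monomer copies are found as non-overlapping local alignments of the
library monomer along the contig (both strands, identity ≥ 75 %),
greedily selected by descending score; accepted hits may overlap by at
most 10 bp so that indel-jittered boundaries of adjacent copies do not
discard whole monomers.  Consecutive same-strand hits separated by at
most 50 bp are chained into arrays — the 50-bp gap operationalizes
"tandemly arranged without inserts" while allowing small indel slack.
`n_monomers` counts complete copies (alignment covering ≥ 90 % of the
monomer); partial trailing copies extend the span but not the count, so
the screen's "at least one / three monomers" criteria read as complete
copies.  An array is flagged as a large TR when the monomer is shorter
than 2 kb and the array span exceeds 3 kb: thirteen abutting 234-bp
monomers (3042 bp) qualify, twelve (2808 bp) do not.

For pre-expanded references (telomere), `n_monomers` counts chained hits
rather than 6-bp units — a documented limitation; the screen never uses
the telomeric family.

## Co-occurrence screen

A contig is positive when it carries (a) at least `min_monomers`
complete monomers of the chosen satellite family — one for the major or
minor satellite, three for the short TRPC-21A monomer — and (b) an
ERV-derived fragment strictly longer than 400 bp.  TE hits are filtered
with the BLAST-style rule: discard only when e-value > 1e-10 AND score
< 100.  E-values use ungapped Karlin–Altschul statistics: λ is solved
exactly for the scoring scheme under uniform base composition
(λ ≈ 0.637 for +2/−3) and K is fixed at 0.1, a conventional magnitude —
computing K exactly buys nothing here because the score threshold
dominates the rule at these search-space sizes.  Both thresholds are
flags and `score_only` bypasses e-values entirely.

The phrase "ERV fragment of length > 400 bp (LTR)" is grammatically
ambiguous; the default reading lets any ERV-derived fragment (internal
or LTR) qualify, and an `ltr_only` flag implements the narrow reading.
Structure maps partition the whole contig into maximal intervals
labelled TR / TE-internal / TE-LTR / unannotated; where features
overlap, the higher alignment score owns the interval.  Every emitted
verdict is re-derived from the emitted evidence as a self-audit
assertion.

## Synthetic data: what it emulates and what it does not

The generator is the source of ground truth for all tests.

* **Library** — seeded random consensuses at realistic lengths: 234-bp
  major-satellite and 120-bp minor-satellite monomers, a 210-bp
  stand-in for the short previously-classified satellite (its true
  monomer length is not public; 210 bp is a typical short satellite
  monomer), (TTAGGG)₂₀, a 6.4-kb LINE, a 150-bp SINE, three ERV classes
  as LTR–internal–LTR elements of ~5.5–6 kb with LTRs of 450–520 bp,
  and a 1-kb DNA transposon.  Random sequences are mutually dissimilar
  (pairwise identity < 55 %, verified in tests with an independent
  aligner); satellites are AT-rich (36 % GC), background is 41 % GC.
* **Reads** — 37-bp paired-end mates of lognormal inserts (median
  100 bp, σ = 0.35), family drawn from a multinomial over the
  chromocenter composition (major satellite 0.662, minor 0.044, other
  satellite 0.009, telomere 0.001, LINE 0.109, SINE 0.021, ERV 0.088
  split by class with IAP 0.022, DNA 0.006; remainder 0.060
  unannotated).  Satellite reads come from 100-copy arrays whose copies
  are independently mutated at 5 % (so junction-spanning reads occur);
  per-base sequencing error is 0.002; base qualities are a constant 38
  (quality variation is not modelled, so QC on synthetic data is a
  pass-through and the QC rules are tested on constructed reads).
* **LINE truncation** — a two-component mixture: 80 % of the 25-copy
  pool expose only the 3'-terminal 2000-bp window, 20 % are full
  length; copies are sampled in proportion to length, as shotgun
  sequencing of a mass pool would.  A continuous 5'-truncation gradient
  is deliberately not modelled — the mixture is the simplest model that
  makes the sub-element enrichment detectable and tunable.
* **Contigs** — explicit blueprints (satellite arrays, exact TE
  fragments, random spacers) whose intended screen verdict is computed
  by direct application of the positivity rule; TE fragments are
  planted exactly so boundary lengths (400 vs 401) are meaningful.
* **Seeding** — each generator (library, reads, contigs) derives its
  stream from `SeedSequence([domain, seed])`.  The domain separation
  matters: with a shared stream, "random" contig spacers replay the
  same uniforms that produced the library and acquire genuine ~95 %
  identity to consensus segments.

Consequently, passing tests show that the algorithms recover planted
truth under realistic composition, divergence and error; they do not
show robustness to real satellite higher-order structure, CpG-biased
mutation spectra, adapter contamination, quality-correlated errors, or
homology between real repeat families (e.g. shared segments between ERV
families), all of which are absent from the generator.

## Problem sizes and numerical choices

Composition recovery is checked at 100,000 reads (multinomial standard
error ≈ 0.15 points on the major satellite, well inside the ±1.5-point
acceptance band) and sub-element localization at 50,000 LINE reads;
both sizes give comfortable statistical margins while keeping the whole
suite fast on a single CPU.  The alignment kernels are exact integer
dynamic programming (no floating-point scores), so determinism is
bit-level: identical seeds give byte-identical FASTQ, composition
tables, and verdicts.  Degenerate inputs are defined, not special-cased:
empty read sets give zero-denominator tables, empty contig sets give
zero counts, all-zero profiles give no segment calls, and queries too
short to seed fall back to exhaustive alignment when the problem is
small enough (and raise otherwise).
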