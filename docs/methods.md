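# Methods

This note records the models, conventions and numerical choices behind
`microsat`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and the catalog

All internal coordinates are 0-based half-open. The TRF `.dat` and
RepeatMasker `.out` dialects are 1-based inclusive and are converted on
ingest; BED input is taken as already 0-based.

The native detector compares each base to the base one unit earlier for
every unit size u ∈ {1..5}, scores comparisons +2 (match) / −5
(mismatch), and reports Ruzzo–Tompa maximal scoring segments. The first u
bases of a tract count as matches, so a perfect tract of length L scores
2·L and the minimum score of 14 makes a 7-base perfect repeat the
shortest reportable locus at every unit size. Purity is
matches / (L − u): 1.0 iff the tract is a perfect repetition. The
detector deliberately models no indels inside the tract — this keeps it
exactly checkable against an exhaustive brute-force scorer (the test
suite does exactly that), at the cost of not claiming parity with TRF's
wraparound dynamic programming; TRF output is instead supported through
the `.dat` parser.

Redundant hits are reduced greedily in priority order (score, then tract
length, then leftmost start, then smaller unit, then unit string): a
candidate overlapping an accepted hit with the same canonical unit, or
contained in / containing an accepted hit, is dropped. The extra
tie-breaks beyond score/length/position are needed because a tract is
often detected identically at its period and at a multiple of it (an AC
repeat at u = 2 and u = 4 with equal score); the smaller unit is the
canonical description. Units are canonicalized to their lexicographically
minimal rotation; reverse-complement units are *not* merged, since calls
are made against the reference strand.

Exclusion filters add flags rather than deleting loci, so they commute
(covered by a property test): `re_proximal` when the gap between closest
edges of a locus and a repetitive-element annotation is ≤ 20 bases
(overlap counts as 0; `Simple_repeat` / `Low_complexity` annotations are
dropped first, being microsatellites themselves), `heterochromatic` for
loci on chromosomes where unique mapping is unreliable (names ending
`Het` plus `U` under the fly r5 naming), and `low_purity` below an
inclusive 0.80 floor. Boundary semantics are fixed as ≤ 20 bases
(proximity), ≥ 0.80 (purity), and strictly > 5% (per-arm residual
heterozygosity). Any flag excludes a locus from all downstream analyses.

## Allele-length genotyping

The anchors are the last left-flank base (position start − 1) and the
first right-flank base (position end). Both must be aligned, non-gap read
bases; the allele length is the count of read bases strictly between
them. Insertions abutting the anchors from inside count toward the
allele; insertions outside the anchors break flank-match runs. An aligned
but mismatched anchor base counts as a flank mismatch (the read still
spans); an anchor covered only by a deletion makes the read unanchored. A
locus flush against a chromosome end can never be spanned.

Flank matching scans outward from each boundary and stops at the first
mismatch, gap, or read end; scorability requires at least `min_flank`
consecutive matches on *both* sides. The default `min_flank` = 3 reflects
the trade-off in the filter sweep (stricter filtering costs more
completeness than it buys concordance beyond three); `min_flank` = 1
reproduces the permissive initial setting. Unique mapping is
operationalized as MapQ > 0 and no alternative-hit (`XA`) annotation.
Base qualities are read but not used: quality-based filtering separates
discordant reads poorly.

Calling requires ≥ 2 scorable reads; the genotype is the modal allele
length and concordance is R_major / R_total. An exact modal tie yields
`ambiguous_tie` and no genotype: the panels are homozygous by design, so
a tie signals error rather than heterozygosity. Heterozygous (two-allele)
calling is out of scope.

## QC metrics

Completeness and concordance are binned by reference length, unit size or
purity class; per-bin values are per-line means averaged over lines
(each genome weighted equally; pooled aggregation is available).
Smoothing is an unweighted running mean over existing integer bins within
±2 bases, truncated at the ends.

Read-length comparisons genotype one line independently per read-length
group; only loci *called in both groups* are comparable, and those with
differing majority alleles are reported with per-group deviations from
the reference length. The bias bootstrap resamples those discordant loci
with replacement (the locus is the sampling unit, jointly across groups),
tabulates per-bin delta frequencies per trial, and reports the
2.5th/97.5th percentiles over 1000 trials. It is deterministic under a
seed, which is recorded in the result. Calibration: under a null where
both groups share one delta distribution (four bins with probabilities
0.15–0.35, 1000 loci — comparable to the ~1000 discordant loci per line
the design anticipates), the bands cover the generating frequencies at
close to the nominal 95%; the acceptance suite verifies 93–97% over 200
repetitions.

MapQ diagnostics correlate per-length-bin mean locus MapQ with mean
concordance (Pearson on bin means, within length strata; undefined with
fewer than two bins) and, for loci with an n:1 allele multiset (n ≥ 4),
report the mean relative MapQ difference of the discordant singleton
versus the majority reads.

## Population summaries

Per locus, the modal allele across lines (ties toward the smaller
allele), the distinct-allele count, and the deviations of non-modal
alleles from the mode; loci called in fewer than two lines are skipped.
Deviations are measured against the population's modal allele, not the
reference. Mononucleotides are excluded from the comparative analyses
(units 2–5); length bins with fewer than 25 loci are suppressed in the
variability tables. The in-phase analysis restricts to purity-1.0 tracts
by default and reports, per unit size and modal-length bin, the
percentage of deviations that are exact unit multiples. The unit-delta
histogram uses ≥ 90% purity and per-unit minimum modal lengths
{2: 13, 3: 20, 4: 23, 5: 27} — the lengths where whole-unit mutation
dominates — with mass at fractional positions resolving 1/unit.

`plateau_length` makes "approaches a plateau" operational: the asymptote
is the mean over the top quartile of length bins, and the plateau is the
smallest length whose (smoothed) percent-in-phase first reaches 95% of
it. On simulated panels whose slippage switches on at a programmed
length, this recovers the programmed value to within ±2 bases.

## The synthetic-data generator

The generator emulates the study design the analyses assume, not any real
dataset:

* **Reference.** Random chromosomes with planted perfect and imperfect
  tracts (units 1–5), separated by at least twice the longest read length
  of unique flank. Default tract lengths are geometric (median ≈ 11
  bases, ~90% below 23, capped at 60); interruptions are planted away
  from tract edges and truth purity is recomputed exactly. A guard zone
  of repeat-breaking bases surrounds each tract, and a verification pass
  redraws guard bases until the detector recovers each perfect plant at
  its exact coordinates — this is what "unique flank" means here, and it
  is what makes catalog recovery a sharp (100%) expectation rather than a
  statistical one. Plants whose whole tract carries a second, shorter
  full period (e.g. a 7-base penta tract that is also period 4) are
  redrawn as inherently ambiguous.
* **Panel.** Homozygous lines; per (locus, line) a Poisson number of
  mutation steps with rate `intensity · ref_length · purity /
  unit_length` (default intensity 0.01 per base — with ~20 lines this
  leaves most short loci monomorphic while longer tracts are frequently
  variable). Steps are ±1 unit with probability `whole_unit_fraction`
  (default 0.9, matching the dominance of whole-unit change in real
  repeat variation), otherwise ±1–2 bases chosen never to be a unit
  multiple; contractions below one unit are rejected. An optional
  per-unit threshold length switches loci between pure non-unit and pure
  whole-unit mutation, giving a programmed plateau for recovery tests.
* **Reads.** Drawn uniformly along each line's mutated chromosomes
  (default 75 bases at 20×, the panel's typical depth) and emitted
  *pre-aligned* in reference coordinates: the generator simulates the
  output of the mapping step rather than running an aligner, keeping
  tests hermetic. Each spanning read's CIGAR places the allele-length
  indel at a uniformly random position inside the tract, so downstream
  gap invariance is genuinely exercised. Error processes: i.i.d. (or
  position-ramped) substitutions, ±1-base slippage per traversal of
  homopolymer tracts (default 2%), and a configurable fraction of reads
  reassigned to a different same-unit locus with MapQ degraded to 10–30
  (default 1%) — flank mismatches then arise naturally, which is what the
  flank filter exploits.

What passing tests therefore show: the scoring rules, metrics and
summaries behave exactly as specified on data whose generative structure
matches their assumptions. What they do not show: robustness to real
aligner pathologies (soft-clip conventions at structural variants,
reference bias in gap placement, PCR stutter correlated across reads from
one fragment), to paired-end rescue of repeat-anchored mates, or to
residual heterozygosity beyond the per-arm exclusion model.

## Problem sizes and numerics

The acceptance-scale runs use 200 planted loci across 3 chromosomes with
20 lines at 20× (error-free recovery), 20 replicate noisy fixtures of 50
loci × 5 lines (filter monotonicity band: mean concordance change per
flank step must not fall below −2 standard errors), panels of 240–600
loci × 40 lines (in-phase and plateau statistics), 200 × 1000-trial
bootstrap repetitions, and 1000 ~2 kb sequences with 8000 planted
repeats (catalog oracle). These sizes make every stochastic check
well-resolved (binomial standard errors of ~1 percentage point on the
headline fractions) while a full test run stays within a couple of
minutes.

All randomness flows from explicit seeds through `numpy` generators;
reruns are byte-identical (fixture manifests carry content hashes and the
config). Ties are broken deterministically everywhere (documented above
per analysis). Degenerate inputs — empty catalogs, empty streams,
unspannable loci, loci at chromosome edges, empty discordance sets —
return empty results or explicit statuses rather than raising, except
where the input is unusable (no records to bootstrap, malformed parser
rows, which raise with the offending line number).

## Known limitations

* The native detector's score convention is calibrated to the 7-base
  minimum locus, but it is not TRF: imperfect-repeat boundaries can
  differ from TRF's alignment-based boundaries. Use the `.dat` parser for
  TRF parity.
* Genotypes are single-allele (homozygous) by design.
* The mismap model reassigns whole reads between same-unit loci; real
  mismapping has richer structure (paralogs, segmental duplication).
* Reference sequences are held in memory as strings; genomes far beyond
  desk scale would want an indexed-FASTA path through the same interface.
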