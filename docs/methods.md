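# Methods

## Translocation calling (CluMP)

The caller assumes coordinate-sorted, aligned paired-end reads from a
hybrid-capture experiment in which at least one side of each
rearrangement of interest is baited. Evidence comes in two forms:
*discordant mate pairs* (mates on different chromosomes, or an insert
size at least `min_insert` apart on the same chromosome) and
*soft-clipped reads* whose clipped bases continue on the partner locus.

Stage by stage:

1. **Extraction.** A template contributes one discordant pair iff both
   mates have MAPQ ≥ `min_mapq` (default 30), neither is duplicate-flagged,
   and the pair is inter-chromosomal or has insert ≥ `min_insert`
   (default 5,000 bp, inclusive). Anchors are canonicalised so that
   anchor A ≤ anchor B under (chromosome, position) ordering. Unsorted
   input is a hard error; templates whose mate never appears are counted
   and skipped.
2. **Clustering.** Single linkage within each (chromosome A,
   chromosome B, mate-orientation class) group: two pairs link iff their
   A anchors are within `cluster_window` (default 1,000 bp) **and** their
   B anchors are. Cluster windows are the min/max anchor extents.
   Pre-sorting pairs by anchors makes the result independent of input
   order.
3. **Clip evidence.** Within each cluster window padded by
   `breakpoint_pad` (500 bp), a read qualifies iff MAPQ ≥ `min_mapq`,
   mean base quality ≥ `min_baseq` (default Phred 20, averaged over the
   read — the gate needs an aggregation rule and the mean is the least
   surprising one), it is not a duplicate, and its *mismatch fraction* —
   soft-clipped bases plus the aligned-base edit distance (NM), divided
   by read length — is ≥ `min_mismatch_frac` (default 0.33). Each
   soft-clip of a qualifying read yields one evidence record carrying the
   1-based junction-side coordinate (the first aligned base for left
   clips, the last for right clips) and the clipped sequence.
4. **Refinement.** Per side, the breakpoint is the modal clip coordinate
   (ties → smallest coordinate). The consensus clip is the per-position
   majority base over the clipped sequences anchored at the junction
   (left clips are reversed so position 0 is always junction-adjacent;
   base ties → lexicographically smallest; length = longest contributing
   clip, re-emitted in reference orientation). A side without clips
   falls back to the window midpoint and the call is marked
   window-resolution. Non-duplicate clip read counts are the number of
   distinct read names per side.
5. **Filtering.** Calls are marked (never deleted) `blacklist` when
   either breakpoint lies in a blacklist interval, `ig_internal` when
   *both* breakpoints lie inside Ig-locus intervals (intra-Ig
   rearrangements are the clonotype pipeline's job), or `low_support`
   when there are fewer than `min_pairs` (default 2) pairs and no clip
   evidence. The operation is idempotent.

Coordinates are 1-based inclusive everywhere in memory (SAM
convention); all BED input/output is 0-based half-open, converted at the
file boundary only.

A note on `min_insert`: the assay's documented threshold is five
thousand; a megabase-scale reading would exceed any capture target and
contradict how "large insert" is used, so the default is 5,000 bp and
the comparison is inclusive (≥).

## Verification

The confirmation rules form a total, deterministic three-way
classifier over clip evidence at the two partners:

* **confirmed** — ≥ 2 non-duplicate clips at each partner with at least
  one mutually concordant pair per partner; or, with a paired
  targeted/WGS sample, ≥ 1 clip at each partner concordant with the
  paired sample's clips while the paired sample has ≥ 5 non-duplicate
  clips at a partner;
* **equivocal** — any remaining clip evidence (a single soft-clipped
  read is suggestive, not definitive);
* **absent** — no clip evidence.

Concordance is exact agreement over the junction-anchored overlapping
prefix of two clipped sequences, requiring overlap ≥ 10 nt. The
original review practice says "the same misaligned sequences" without a
tolerance; exact match over a 10-nt floor is the strictest rule that
still accepts staggered reads of different clip lengths. The
"equivocal" bucket is defined operationally as evidence that fires
neither confirmation rule. A coverage drop at the unbaited partner is
carried as an annotation but deliberately not used in the status logic,
because the confirmation rules do not require it. Non-duplicate
counting uses the duplicate flag plus collapse of identical
(coordinate, side, sequence) stacks from the same read name.

Status is monotone: adding a concordant non-duplicate clip can only
promote absent → equivocal → confirmed (property-tested).

## V(D)J candidate filtering

Clonal fractions are always recomputed as clone count over the summed
counts at the same (sample, locus) before filtering; assembler-reported
fractions are not trusted. The cascade order is fixed: pseudogene
removal → fraction recompute → fraction filter (> 0.10, strict) →
cohort specificity filter (exact CDR3 nucleotide identity, occurrence
≤ 5 samples, inclusive) → count filter (> 50 in cell-line mode, > 10 in
patient mode, strict). Two deliberate choices:

* The specificity filter counts occurrences among **post-fraction-filter
  candidates**, not the raw clone universe: the filter targets recurrent
  prominent sequences (polymorphisms and capture artifacts), and
  counting the raw universe would let one noisy sample poison the
  cohort. The counting universe is stated explicitly because it changes
  results.
* Samples from the same donor are **not** collapsed when counting
  occurrences; the threshold of 5 is required even then.

Patient mode changes only the count threshold; the fraction threshold
stays at 0.10. The pipeline output is stable-sorted by (−count, CDR3)
and is invariant to input row order.

## Sensitivity statistics

`sensitivity_ci(detected, total)` implements a Wald normal-approximation
binomial interval with z = 1.96, with a specific rounding recipe: the
point estimate is rounded to 2 dp *first*, the margin is computed from
the rounded estimate, and the bounds are rounded to 2 dp and **not**
clipped to [0, 1] (1/2 legitimately prints 0.50 (−0.19–1.19)). This is
the only recipe consistent with the published per-family values this
package reproduces; one published row, 3/4 printed as (0.35–1.15), is
inconsistent with it (the recipe gives 0.33–1.17) and is treated as a
typographical erratum — it is documented here and excluded from the
reproduction test rather than matched.

Detection matrices score every marker against every condition's
verified calls: translocation markers match a confirmed (or, by
default, also equivocal) call whose breakpoints agree within ±10 bp —
exact clip-sequence matching is how single-read detections are credited
in practice, and the tolerance covers window-resolution calls —
clonotype markers match by exact CDR3. `lowest_detected_dilution`
reports the most dilute detected condition without requiring
contiguity, since real dilution series show gaps.

## Probe design

V segments yield 3′-anchored probes of the last `probe_len` (120) nt, J
segments 5′-anchored probes of the first 120 nt — junction-spanning
fragments are captured from either side — and C-region exons are tiled
with full-length 120-nt probes (last tile anchored to the 3′ end).
Probes are emitted in segment (coding) orientation: capture is
strand-agnostic, and genomic strand travels separately in the optional
BED output. Segments shorter than `probe_len` but at least
`min_segment_len` (40 nt) yield a full-length probe rather than being
dropped, maximising recall. Duplicated sequences (alleles sharing an
end) collapse to one probe, keeping the lexicographically smallest id.
The promiscuity screen is a constructed criterion — the assay removed a
handful of cross-hybridising probes without stating a formula — and
flags a probe when more than `promiscuity_max_hits` (5) other probes
share at least one exact `promiscuity_k`-mer (k = 25) with it.

## Simulator

The read simulator emulates the dilution-series design: a derivative
chromosome joins the baited A side to partner B, each fragment is
tumor-derived with independent probability `tumor_fraction`, fragment
lengths are Normal(300, 30) (150 mimics cell-free DNA), reads are
150 bp, and fragments are drawn within ±`capture_span` (1,000 bp) of
the bait — tumor fragments around the junction on the derivative,
normal fragments around the unrearranged baited locus. Junction
reads are emitted pre-aligned with soft-clip CIGARs against the side
holding the majority of their bases; no aligner is in the loop, which
isolates the caller under test from aligner behaviour. Base qualities
are Normal(35, 3) clamped to [2, 40]; PCR duplicates are injected at
2 % as flagged copies. Every byte of output is a function of the
config, and each output stream has its own RNG namespace derived from
the master seed.

What the simulator does **not** model: sequencing errors beyond base
qualities, capture-efficiency/GC bias, fragment-length bias at the
junction, somatic hypermutation, micro-homology or untemplated bases at
junctions, and aligner artifacts (multi-mapping, clip mis-placement).
Passing tests therefore demonstrate the algorithms' correctness on
clean evidence and their sampling-limited behaviour at low dilution,
not robustness to alignment noise on real data.

The clone-cohort simulator plants one dominant clone per locus (raw
weight drawn from (0.3, 0.9)) plus ~20 artifact clones with weights
log-uniform over [0.005, 0.5] — matching the observation that false
clonotypes span that fraction range skewed low — then normalises
per locus and converts to counts at a per-locus depth of 1,000–3,000
reads. A configurable number of artifact CDR3s recurs across
`shared_in` samples (default 8 of 10, capped at the cohort size) to
exercise the specificity filter; shared artifacts may be given their
own weight range so fixtures can make them decisively prominent.

## Problem sizes

The test suite and acceptance script run the full pipeline at 20,000
fragments per run (≈ 40,000 reads), 20 seeds for recovery and for each
of four dilutions, and 50–200 simulated cohorts for the filter cascade —
sizes at which the binomial sampling regime of the dilution series is
clearly visible while a complete run stays under a minute per suite on
one CPU.

## Known limitations

* Orientation handling is simplified: the simulator and caller treat
  junctions as head-to-tail joins; inversion-type (FF/RR) junction
  consensus logic is exercised only lightly.
* The promiscuity screen and the breakpoint-refinement tie-breaks are
  this package's own constructions where the original assay left the
  mechanism unstated; they are deterministic and documented but not
  validated against the original probe set.
* Patient-scale behaviour (contamination, clonal heterogeneity,
  cell-free DNA fragmentation biases) is outside the simulator's scope.
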