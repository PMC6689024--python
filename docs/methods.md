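# Methods

## Coordinate convention

All results are expressed in protospacer coordinates on the protospacer
strand: positions 1–20 run 5′→3′ along the protospacer, the PAM occupies
21–23 (20-nt spacer, 3-nt PAM defaults; both lengths are fields of
`TargetSite`), downstream of the PAM continues 24, 25, …, and upstream of
the protospacer is −1, −2, … with −1 immediately adjacent to 1.  **There is
no position 0**: published editing tables report a "position −1" directly
before position 1, and the no-zero convention keeps those labels intact.
Conversion is always called on the protospacer strand; for a minus-strand
protospacer a C→T event appears as G→A on the amplicon forward strand and
is re-oriented during tabulation.

The quantification window runs from 30 nt upstream of the PAM's 5′ end
(i.e. the whole protospacer plus ten further upstream bases, for the
default 20-nt spacer) through 10 nt downstream of the PAM's 3′ end — 43
positions for the canonical geometry, and `30 + pam_len + 10` in general.
The "30 nt upstream" is measured from the PAM start rather than the
protospacer start because only that reading yields the 43-bp total.

Amplicon references must be plain ACGT; IUPAC ambiguity codes are rejected
rather than expanded, since amplicon references are short and known
exactly.  Site annotations locate the protospacer in the FASTA record by
exact match and require exactly one hit.

## Read quantification

* **Demultiplexing** is exact prefix matching of equal-length barcodes
  (0 mismatches); non-matching reads are counted as unassigned.  This is
  the simplest defensible demultiplexer for designed inline barcodes.
* **Quality trimming** removes bases from the 3′ end while their Phred
  score is below `q_min` (default 15).  This is the standard read-trimming
  operation; window-average filtering was rejected as a less direct
  reading of a per-base quality threshold.
* **Placement** matches the first 20 bases of the (trimmed) read exactly
  against the amplicon or its reverse complement.  Zero, two or more seed
  hits discard the read (counted separately); a unique hit is extended to
  a full-length gapless comparison and accepted if the mismatch fraction
  is ≤ 0.2.  The generous mismatch tolerance accommodates heavily edited
  windows (a fully edited 43-bp window can carry a dozen real
  substitutions); gapped alignments are not attempted because the
  frequency model has no indel term — reads that cannot be placed
  ungapped are discarded and counted.
* **Tabulation** increments the observed-base count at every window
  position a read covers; depth may vary by position.  Positions with
  depth 0 are *missing*, never 0 % — reporting zero editing where there is
  no evidence would fabricate non-edits.  A minimum-depth option (default
  1 in the library, 100 in the CLI quantifier, where real amplicon data
  are expected) masks frequencies measured at lower coverage as `NA`.

The batch engine vectorizes all four stages over equal-length read
matrices; a per-read path implements the identical semantics and the two
are cross-checked on random batches in the test suite.

## The read simulator

The generator emulates targeted amplicon sequencing of an edited locus:

* Each read spans the quantification window plus a 20-nt 5′ flank (the
  flank gives the placement seed an edit-free anchor, as primer-adjacent
  bases do in real amplicons) and an optional 3′ flank.
* Per read and per reference cytosine, C→T conversion fires independently
  with probability `q = min(1, p_edit(cp) · NC_mult · CN_mult)`; clipping
  events are counted.  Context modulation defaults to the upstream (NC)
  dinucleotide only — the dominant signal in published preference tables —
  with the downstream map defaulting to no effect.
* Every base (barcode included) is then substituted uniformly to one of
  the other three bases with probability `seq_error` (default 0.001,
  ~Q30-grade data); qualities are constant (default Q37) apart from an
  optional low-quality 3′ tail used to exercise trimming.

The expected T fraction at a cytosine is therefore exactly
`q(1−e) + (1−q)e/3`, which the simulator records as ground truth.

**What is not modeled** (and hence what passing tests do not show about
real data): editing co-occurrence/processivity within a read, indels,
PCR duplicates and chimeras, paired-end structure, Cas9-independent
deamination background, and non-uniform quality/error profiles.  The
simulator validates the analysis algebra, not wet-lab artefact handling.

Built-in archetypes mirror the window classes seen across published
editors: `forward` (positions 1–8 at 0.6), `backward` (9–13 at 0.6),
`broad` (1–14 at 0.5) and `gc_averse` (2–12 at 0.7 with GC multiplier 0.1
vs 1.0 for AC/TC and 0.7 for CC).

Synthetic sgRNA panels are *designed*, not random: every requested
protospacer position receives a cytosine in a controlled number of panel
members with balanced upstream contexts, and (for window-recovery studies)
every guide carries at least one cytosine inside the region of interest —
the way a real editing panel is chosen to contain editable targets.
Random panels would leave positions uncovered and would include guides
with no editable C, whose per-guide normalization then amplifies noise
into spurious window calls.

## Window statistics

Normalization divides each sgRNA's C→T frequencies by its maximum, so the
best-edited cytosine is exactly 1; sgRNAs whose frequencies are all
missing or zero are flagged "no editing" and excluded from averaging
(an optional `min_signal` floor extends the flag to noise-level maxima).
The per-position mean runs **only over sgRNAs that carry a cytosine at
that position**; averaging zeros for absent cytosines would bias the
window toward panel composition rather than editor behaviour.  CEW
membership is strict (> 0.6) while scope membership is inclusive (≥ 0.40),
matching the wording of the two rules ("exceeding" vs "≥").  The CEW is
reported as a set — interior gaps are preserved — with min/max alongside.

The FSCBE/BSCBE/BRCBE decision rule is: empty CEW → inactive; span ≥ 12
positions, or reaching both position ≤ 2 and position ≥ 9 → broad-range;
otherwise starting at position ≥ 7 → backward-shifted; otherwise
forward-shifted.  No formal rule exists in the literature — published
assignments are descriptive — so the thresholds were chosen to reproduce
the published groupings of known windows (1–8 forward, 9–13 backward,
1–14 broad, 4–8 classic forward) and are exposed as configuration.

## Substrate preference

Sites enter the analysis on the normalized scale (comparable across guides
of different absolute activity).  A position class qualifies when any site
there reaches 0.8 normalized frequency; all sites at qualifying positions
are analyzed, grouped by NC and, separately, CN dinucleotide — both
directions are computed because either may carry the preference signal.
Group differences use classical fixed-effects one-way ANOVA,
`F = (SSB/(k−1)) / (SSW/(N−k))`, with empty groups excluded; degenerate
panels (fewer than two non-empty groups, or no within-group degrees of
freedom) are flagged rather than raised through the pipeline.  Zero
within-group variance with unequal means reports F = ∞, p = 0, flagged.
Orderings join group means closer than 0.05 (absolute, on the normalized
scale) with "/" — the tie tolerance is a package choice, as published
orderings never define when two contexts tie — and non-significant panels
(p ≥ 0.05) print `N.S.`.  No multiple-testing correction is applied across
editors, matching standard practice for these descriptive tables.

## Specificity

`(onCʰ − offCʰ)/onCʰ` with onCʰ/offCʰ the highest C→T frequency among
covered window cytosines of the on-/off-target (smallest position on
ties).  Each off-target is scored in its own 43-bp protospacer window —
off-target loci are imperfectly matched protospacers with their own PAMs.
`no-activity` fires when onCʰ is undefined or below `min_activity`
(default 0.05; "no obvious activity" is never quantified in the
literature, so the floor is explicit configuration); `N.Sp.` fires when
offCʰ > onCʰ, with the negative value still recorded.  When one on-target
has several off-targets, per-pair scores are primary and the minimum
(worst case) is the per-target summary, since the aggregation used in
published single-number-per-locus tables is unstated.

## Validation studies and problem sizes

The seeded studies in `cbekit.evaluation` (run by the test suite and by
`scripts/acceptance.py`) use desk-scale sizes chosen so binomial noise is
far below every decision threshold: 10,000–20,000 reads per sample
(frequency SD ≤ 0.005), panels of 4 guides for classification, 9 for
window recovery (covering positions 1–14, anchored in the designed
window), and 6 guides with three sites per even position for preference
(≥ 5 sites per context group).  Classification and preference recovery use
100 seeded replicates; the ANOVA is checked against an independent
sums-of-squares oracle on 1,000 random instances and calibrated under a
null with no context effect over 1,000 replicates.  The null study samples
binomial conversion counts at the placed-depth level directly (the
sampling distribution the read-level pipeline produces at fixed depth)
rather than materializing 10⁷ reads; read-level and frequency-level
sampling agree by construction at the cytosine positions, which the
frequency-recovery study verifies end to end.

## Numerical and degenerate-input choices

* All randomness flows from a single seed; per-stage seeds are derived by
  a fixed integer hash, and identical configurations reproduce
  byte-identical outputs.
* Normalization is exactly idempotent (the maximum maps to exactly 1.0).
* Frequencies are exact ratios of integer counts; no pseudocounts.
* Ties: highest-conversion positions report the smallest cp; ordering
  tiers compare each mean to the current tier head, so tie chains do not
  bridge tiers.
* Empty reads after trimming, reads shorter than the seed, ambiguous
  seeds, and placements running off the amplicon are discarded and
  counted, never silently dropped.

## Known limitations

Placement is exact-seed, gapless and single-amplicon — it is a
quantification-window placer for amplicon data, not a read mapper; indel
alleles are invisible by design.  Substrate preference uses dinucleotide
contexts only (no WRC-style trinucleotide motifs).  The classifier encodes
one defensible formalization of window classes; editors with unusual
gapped windows near the decision boundaries may be sensitive to its
thresholds.  Simulator realism limits are listed above.
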