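# Methods

This note documents the models, conventions and numerical choices behind
`reptimemut`, and what its synthetic test bed does and does not establish
about real data.

## Replication-timing model

The timing map is a per-chromosome list of (position, minutes) anchors at
a nominal 500-bp spacing, as in published origin-firing timing profiles
for budding yeast. The time at an arbitrary position is obtained by
linear interpolation between the flanking anchors:

    time = time1 + (time2 − time1) · (pos − pos1) / (pos2 − pos1)

Positions before the first or after the last anchor of a chromosome (in
practice the first and last few hundred base pairs) are *not covered*:
records there are excluded and counted, never extrapolated. The scalar
and vectorised interpolators evaluate the identical expression, so their
results are bit-identical — a property the test suite checks against an
independent per-base expansion of every anchor interval.

### Equal-sequence bins

The genome is partitioned into early/middle/late terciles — and nine
nested sub-bins — each covering the same amount of *mapped* sequence.
Each anchor interval contributes its bp span at its midpoint time (the
record granularity of the map itself); intervals are pooled across
chromosomes, sorted by time, and cut at cumulative-bp fractions k/9.
The cut value is the midpoint time of the first interval whose
cumulative span strictly exceeds the target fraction, so an interval
ending exactly on a boundary belongs to the lower bin and each tercile
is exact to within one interval span (≲0.1% of a realistic genome).
Classification uses half-open intervals: a time exactly equal to a cut
belongs to the higher bin. With the published yeast map these cuts land
at 27.67 and 34.28 minutes; with synthetic maps they are recomputed from
the map itself. Nine-bin indices nest inside the terciles by
construction (cut 3 and cut 6 are the tercile cuts). Maps in which the
cuts are not strictly increasing (e.g. all times equal) are rejected as
degenerate rather than silently binned.

The nine-bin regression abscissa is the mean interpolated time over the
covered, unmasked bp of each bin, computed during the sequence census.

## Sequence census and expected counts

For every covered, unmasked position with a full A/C/G/T trinucleotide
window, the census tallies the pyrimidine-strand trinucleotide (32
classes) of its middle base per bin; windows containing N are skipped.
A parallel dipyrimidine census counts positions whose base and successor
are both pyrimidines or both purines — the lesion-capable dinucleotides
on either strand.

Expected mutation counts per bin answer "what would composition alone
give?": each 96-channel rate is estimated from the pooled covered genome,
r_c = observed_c / Σ_bins census[t(c)], and applied to each bin's census.
Because channels sharing a trinucleotide share its census, this is
algebraically identical to estimating per-trinucleotide rates; the
per-channel path is kept as the single code path. Expected totals equal
observed totals by construction, which makes the chi-square goodness of
fit well-posed with df = bins − 1. Observed bin counts include the few
SBS whose channel is undefined (N in the window, chromosome end); the
expected vector is rescaled to the observed total, a sub-0.1% correction
on realistic data.

## Mutation spectra and similarity

Spectra use the standard 96-channel convention: six pyrimidine-strand
substitution classes × 16 flank pairs, COSMIC channel order. Purine
references are reverse-complemented together with their flanks. Records
whose reference allele disagrees with the genome are skipped and counted
(`n_ref_mismatch`), tolerating call-set/assembly drift without aborting.
Similarity between frequency vectors is the cosine (dot product over the
product of magnitudes) or the squared Pearson correlation; signature
screens report one cosine per catalogue column, flagging > 0.75 as high
and > 0.59 as marginal similarity.

## Complex mutations

A complex event is a maximal chain of ≥ 2 mutations in one isolate on
one chromosome in which each member lies within `max_gap` bp (default
10, *inclusive* — the plain reading of "within 10 bp"; the boundary and
the gap are configurable) of its predecessor. Chaining is transitive:
positions 100, 110, 120 form one three-member event. Members may be
substitutions or indels; indels are anchored at their 0-based start.
Each record belongs to at most one event, and the caller is verified
against an all-pairs union-find oracle. Timing expectations for complex
members assume they distribute across bins like all SBS; complex spectra
include only the SBS members.

## CPD damage maps

Lesion counts are strand-aware and anchored at the 5' position of the
dipyrimidine on the lesion strand (for minus-strand lesions this is the
higher reference coordinate of the purine pair). Each count is assigned
to both constituent positions, so totals double; lesions whose partner
falls off-chromosome are assigned once and counted as warnings. Bin
summaries sum assigned counts over covered, unmasked positions of both
strands — percentages are therefore unaffected by the doubling — and are
paired with the census dipyrimidine percentages for composition
comparison. Repair is summarised as fraction remaining per bin,
(count_t/s_t)/(count_0/s_0); `s` is 1 by default or the sample totals
under `library_size` normalisation — both modes are provided because the
appropriate between-sample normalisation is data-dependent.

The 1-kb window scan labels a window with a bin only when every position
is covered and falls in that bin; windows with no covered position are
`unavailable`, others `mixed`. The repeat-collapse score is the mean
per-window count over windows overlapping a candidate region divided by
the mean over the remaining windows of the same chromosomes: a repeat
with N genomic copies collapsed onto r reference copies scores ≈ N/r.

## Coordinates and masking

All internal coordinates are 0-based half-open. BED-style inputs are
read as-is; wiggle positions (1-based) are shifted on input; prose-style
1-based inclusive coordinates are converted once, when a mask is built
(`RegionMask.from_1based_inclusive`). The built-in rDNA mask uses the
published chrXII boundaries under that convention — the original
analysis does not state its base convention, so this is a documented
assumption exposed through the constructor. Masking removes any record
sharing a reference base with a mask interval; insertions are tested at
their single anchor base. Masking is idempotent and partitions inputs
exactly (kept ∪ removed = input).

## Statistics

* Chi-square goodness of fit: Σ(O−E)²/E with df = bins − 1 (expected
  totals are constrained to observed). All expected values must be
  positive.
* Nine-bin regression: ordinary least squares of per-bin counts on mean
  bin time; the two-sided p-value uses t = r√(n−2)/√(1−r²).
* Wilcoxon matched-pairs signed-rank: zero differences dropped, exact
  null for ≤ 25 informative pairs, normal approximation (no continuity
  correction) above, two-sided by default with one-sided alternatives
  available since directional hypotheses are common here. Exactness is
  validated against full 2ⁿ enumeration.

No continuity corrections are applied anywhere, and p-values are
reported unadjusted for multiple testing.

## Synthetic test bed

The generator produces a ~1/20-scale yeast-like study: 8 chromosomes ×
75 kb, GC 0.38, i.i.d. bases; timing maps from 2 origins per chromosome
firing uniformly in 10–30 min with 1.5 kb/min forks, sampled at 500-bp
anchors with uncovered chromosome ends; UV-like mutations (C>T dominant,
strongest with a 5' pyrimidine) drawn per site as Poisson with rate
base_rate · weight(trinucleotide) · exp(β · time). β is calibrated from
a target late-vs-early rate contrast via
β = ln(1 + contrast)/(mean late time − mean early time), matching the
~8% (repair-proficient) and ~36% (GG-NER-deficient) contrasts of the
study designs it emulates at their sample sizes (~12,000 and ~23,000
records). Complex events are seeded explicitly (2–4 members within
10 bp, one isolate, rate ∝ exp(β·time)) so caller truth is exact rather
than emergent. CPD profiles are Poisson at dipyrimidines on both strands
(0.05 lesions per site per strand by default); a configurable region's
rates are multiplied by copy_number/reference_copies (150/2 by default)
to emulate the collapsed-repeat artifact as a count inflation rather
than assembled repeats — mirroring how multi-copy reads pile onto a
2-copy reference; the repaired sample is a binomial thinning with
per-bin survival (0.3 by default). Every generator is deterministic
under the config seed with independent, order-insensitive streams.

What the test bed does *not* emulate: real karyotype and chromatin,
origin interference and stochastic firing, sequence autocorrelation,
transcription-coupled repair strand asymmetries, UV photochemistry
beyond dipyrimidine specificity, and read-level noise. Passing tests
demonstrate that the pipeline's computations are correct and that the
designed effect sizes are recoverable at study scale — not that any
particular biological conclusion holds in real data.

Problem sizes in the shipped tests and acceptance script (600-kb
genomes, 100–200 simulation replicates, 1,000-set oracle comparisons)
were chosen as the smallest scales at which the statistical checks have
clear power.

## Known limitations

* Text wiggle only; binary bigWig is out of scope.
* Equal-length multi-base substitutions (MNVs) are rejected at parse
  time rather than modelled; the complex-mutation machinery is the
  intended representation for clustered changes.
* `compute_bins` requires strictly increasing cutpoints; extremely
  coarse or heavily tied maps are rejected as degenerate.
* The per-chromosome expected percentages use genome-wide channel rates
  applied to each chromosome's census; chromosome-private mutational
  processes would violate that assumption.
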