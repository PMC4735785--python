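# Methods

`capfuse` determines patient-specific genomic breakpoints of the
t(12;21)(p13;q22) ETV6-RUNX1 fusion from targeted-capture paired-end
sequencing, interprets them as rearrangement events, and reproduces the
cohort-level statistics of a 26-patient childhood-ALL breakpoint study
from its packaged tables. This note records the model, the numerical
choices, and what the synthetic data does and does not establish.

## Junction model and strand semantics

The central object is a *junction*: an ordered pair of breakends, the
donor segment flowing into the fused joint and the acceptor flowing out.
Strand flags fix which half of each chromosome survives:

| side | `F` | `R` |
|---|---|---|
| donor | forward prefix `[1..pos]` | reverse complement of suffix `[pos..len]` |
| acceptor | forward suffix `[pos..len]` | reverse complement of prefix `[1..pos]` |

For a chr12-donor / chr21-acceptor junction the strand pair maps onto
the four orientation types: `FF → a`, `RR → b`, `FR → c` (the productive
in-frame ETV6-RUNX1 fusion), `RF → d` (the reciprocal product). The
derivative chromosome of each type then carries 0 / 2 / 1 / 1
centromeres respectively — acentric type-a derivatives are mitotically
nonviable, which is why type a is absent from patients while dicentric
type-b derivatives are rare but possible. Centromere overlap is counted
qualitatively (any ≥ 1 bp intersection), since the argument is
presence/absence, not dosage.

Every junction has a mirror representation (read from the other strand
of the derivative): `((c1,p1,s1),(c2,p2,s2)) →
((c2,p2,flip s2),(c1,p1,flip s1))`, an involution. The canonical form
places the donor on the earlier chromosome in natural order
(chr1 < … < chr22 < chrX < chrY), with a full lexicographic tie-break
for intra-chromosomal joints so each junction has exactly one canonical
representation. All external coordinates are 1-based inclusive; BED is
converted at the boundary.

**Microhomology normalization.** When the two sides share bases at the
joint, the breakpoint is ambiguous within that window. The package
reports the split with the smallest donor coordinate ("leftmost-donor"),
recording the full window size as `microhomology_len`. Untemplated
inserted bases that happen to match the adjacent reference are absorbed
into the flanks first. Normalization provably leaves the derivative
sequence unchanged (a property test covers all four strand
combinations); the simulator and the caller share the same normalizer,
so truth and calls are always in the same convention. The published
breakpoint coordinates are treated as data, not re-derived, because the
original reporting convention under microhomology is not stated.

## Event interpretation

Per sample, junctions are grouped: any junction touching a chromosome
beyond the primary pair joins the sample's type-c junction in a
`three_way` event (partners recorded); a complementary c+d (or a+b) pair
is `two_way_reciprocal`; a b+d pair with distinct breakpoint pairs marks
joint breaks of both homologs (`homologous_joint`); leftovers are
`two_way_simple`. A junction whose far breakend lies megabases outside
the capture region but still on chr12/chr21 is a primary-pair junction —
this is required to type every patient in the packaged table correctly.

## FISH prediction

The dual-color panel (green 5′-ETV6 probe, red whole-RUNX1 probe) is
modeled as intervals on a diploid genome. Each event consumes one
homolog of every chromosome it touches (each junction of a
`homologous_joint` event consumes its own); derivatives are laid out
from junction segments; probe fragments at least `min_detectable_bp`
long produce signals, and a detectable green and red fragment on the
same derivative fuse into one yellow signal. This reproduces the
negative pattern (2 green, 2 red) and the classic positive pattern
(1 green, 2 red, 1 yellow). The homozygous two-red/two-yellow pattern is
reproducible only under an explicit `homozygous=True` interpretation and
is not asserted; the three-red count reported for three-way cases is not
fully derivable from the stated probe model and is likewise not an
asserted surface.

## Calling procedure

1. **Mapping.** External SAM/BAM via pysam is the first-class input. A
   built-in mapper (exact 21-mer index, ungapped extension, soft clips
   at the maximal-scoring span with match +1 / mismatch −3; MQ 60 unique
   best, 3 tied, 0 unmapped) makes the test pipeline self-contained on
   toy references; its tie policy is a stand-in, not a claim about the
   original aligner.
2. **Insert model.** Median and 1.4826·MAD of co-chromosomal inward-FR
   separations ("separation" = outer span of the two mates, well defined
   under clipping); a unimodality flag comes from half-height contiguity
   of a 20-bin histogram. At least 100 pairs are required.
3. **Pair classification.** Evidence requires mapping quality strictly
   greater than 30 on both mates. Classes: inter-chromosomal;
   distance-discordant when |separation − center| > 4·spread (two-sided
   — the deviation rule is stated one-sidedly in words, but two-sided
   also catches deletion-like artifacts); orientation-discordant when
   not inward-FR; otherwise proper.
4. **Clustering.** Single-linkage by chromosome pair and orientation
   pattern with positional gap ≤ center + 3·spread on both footprints;
   clusters need ≥ 3 pairs (`min_cluster_pairs`, a specificity choice —
   no published minimum exists — exposed as a flag). Predicted breakends
   are the innermost mate-end coordinates per strand pattern, and the
   observed mate orientations determine the junction strand flags.
5. **Window extraction.** All mapped reads within `window_bp`
   (500–1000, default 750) of each predicted breakpoint, plus unmapped
   reads whose mates map inside the window.
6. **Assembly.** Greedy overlap-consensus (best overlap ≥ 30 bp at
   ≥ 0.95 identity, either orientation, support-weighted majority,
   lexicographic tie-breaks — deterministic). Assembly input is
   restricted to split-read candidates: soft-clipped reads whose clip
   faces the predicted breakend with a clip boundary within 150 bp of
   it, plus window-anchored unmapped reads, capped at 120 reads. This
   keeps reads of a nearby second junction (e.g. the reciprocal partner)
   out of the contig and keeps assembly quadratic cost bounded. The
   contig is then polished by column-majority vote of realigned
   candidate reads (votes only from placements at ≥ 0.9 identity; the
   assembly base survives ties) and trimmed to columns covered by ≥ 2
   reads.
7. **Resolution.** The maximal exact prefix of the contig matching one
   reference locus (either strand) and the maximal exact suffix matching
   another define the joint; overlap = microhomology, gap = untemplated
   insertion; leftmost-donor normalization follows. Anchors may start a
   few bases into the contig so a stray base at a thin contig end cannot
   mask a whole side. A contig explained by a single locus is the
   reference allele ("no junction").
8. **Support.** A read supports the junction iff its contig alignment
   crosses the whole breakpoint window with ≥ 2 extra bases on both
   sides, leaves < 5 unaligned bases at each read end, and its reference
   alignment retains clipped bases ("not fully reference-explained" —
   the literal reading, no reference alignment at all, would reject
   every junction-spanning read with one long mapped side). Junctions
   need ≥ 2 supporting split reads (`min_support_reads`, configurable)
   and carry their split and pair support plus fused flank sequence.

## Synthetic data

The generator emulates the assay, not the chemistry: random toy
chromosomes (~60 kbp each, GC 0.41) with centromere annotations and
6 kbp capture targets; derivative chromosomes built per the strand
semantics, with microhomology engineered by copying donor-end bases just
outside the acceptor breakpoint (so the homology is genuine sequence,
and truth records the actual window after re-normalization); fragment
lengths Normal(375, 35) truncated at 2·read-length (matching the
350–400 bp library and keeping the 4·SD rule well defined — a lognormal
was rejected as needlessly heavy-tailed here); 100 bp FR pairs at
30-fold target coverage; capture as pair-level rejection sampling
(fragment must overlap a target ± 200 bp margin on its source molecule,
including targets projected through derivative coordinates), plus 1%
genome-wide off-target pairs; uniform per-base substitution errors
(default 0.2%); flat base quality. One mandatory seed drives everything;
identical seeds give byte-identical FASTQ.

Not modeled: PCR duplicates, adapters, quality profiles, probe-level
hybridization efficiency, repetitive or low-complexity reference
sequence, and tumor purity (each derivative is covered at full depth).
Passing the recovery suite therefore shows the evidence rules and the
resolution arithmetic are correct under clean capture statistics; it
does not establish sensitivity in repeats, at low purity, or under
real error profiles.

## Cohort statistics

Remission time is read as time-to-event for relapsed patients and
censoring time for patients alive in remission — the only reading
consistent with the relapse-day values. The two-group log-rank statistic
is computed from first principles (observed vs hypergeometric-expected
events over the risk sets at each distinct event time, variance
`d(n−d)n₁n₀ / (n²(n−1))`, χ² with 1 df, two-sided); the published claim
names only "Kaplan–Meier analysis", so the log-rank test is adopted as
the standard companion and is additionally cross-checked against
lifelines in the test suite. Kaplan–Meier curves come from the package's
own estimator. The companion association test is an exact hypergeometric
tail probability evaluated in rational arithmetic and verified against
brute-force subset enumeration. Mean age rounds half-up to one decimal.
One chr21 coordinate in the packaged breakpoint table is stored as
printed alongside a corrected-value column (it lies outside the capture
region and is presumably a transposition); type census uses strand
columns only, so the value does not affect any reported count.

## Problem sizes and determinism

The recovery suite runs seven scenarios (SV-free control, c-only, c+d
reciprocal, b+d homologous joint, three-way, microhomology 0–8 bp,
insertion 0–10 bp) at 20 seeds each on two to three 60 kbp chromosomes —
sizes chosen so the whole acceptance suite completes in about a minute
on one CPU while every junction still receives ~25–45 discordant pairs
and ~20–40 split reads, the same evidence depth a 30× capture experiment
yields. All randomness flows from explicit seeds; hypothesis-based
property tests are derandomized.

## Known limitations

- The caller targets inter-chromosomal junctions; intra-chromosomal
  deletions/inversions are not first-class call types.
- The built-in mapper is ungapped; indel-containing reads rely on soft
  clipping and the assembly step.
- Breakpoints inside long repeats shared between the two loci would make
  the maximal prefix/suffix matches ambiguous; toy genomes are random,
  so this is untested territory.
- FISH prediction is interval bookkeeping; signal intensity, probe
  efficiency and nuclear geometry are out of scope.
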