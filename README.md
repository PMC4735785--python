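# capfuse

Targeted-capture discovery and interpretation of **ETV6-RUNX1 genomic
fusion breakpoints** in childhood acute lymphoblastic leukemia.

The t(12;21)(p13;q22) translocation fuses ETV6 (chr12) to RUNX1 (chr21)
and is the most common chromosomal rearrangement in childhood B-lineage
ALL. The genomic breakpoint — unlike the fusion transcript — is a
stable, patient-specific sequence, which makes it the best target for
minimal residual disease (MRD) monitoring by qPCR. `capfuse` implements
the complete desk-side analysis for a capture-sequencing breakpoint
assay: paired-end reads over the ETV6/RUNX1 capture regions go in;
base-pair-resolved junctions, rearrangement-event interpretations, FISH
pattern predictions, cohort statistics and MRD target sequences come
out. A seeded read simulator with machine-readable truth makes the whole
pipeline testable end-to-end without any external data.

**Who it is for:** bioinformaticians running or evaluating
capture-based fusion-breakpoint assays, and anyone reproducing the
cohort-level analysis from the packaged 26-patient tables.

## The model in brief

A junction is an ordered pair of breakends with strand semantics: donor
`F` keeps the forward prefix ending at the breakpoint, donor `R` the
reverse-complement suffix; acceptor `F` keeps the forward suffix,
acceptor `R` the reverse-complement prefix. For chr12→chr21 junctions
the strand pair defines the four orientation types

```
(F,F) → a    (R,R) → b    (F,R) → c    (R,F) → d
```

with derivative-chromosome centromere counts a:0, b:2, c:1, d:1 — the
acentric type a cannot propagate mitotically, which is why it is never
observed. Calling follows standard discordant-pair + split-read
practice: pairs with mapping quality > 30 that are inter-chromosomal,
deviate from the insert median by > 4 SD, or sit in a non-FR orientation
are clustered; reads within 500–1000 bp of each predicted breakpoint are
extracted; split-read candidates are assembled into a junction contig by
greedy overlap-consensus; maximal exact prefix/suffix matching against
the reference resolves the breakpoint, microhomology window and any
untemplated insertion; a read supports the junction if it crosses the
breakpoint with ≥ 2 extra bases, has < 5 unaligned end bases, and is not
fully explained by the reference.

## Worked example

Simulate a classic reciprocal c+d case, call it, and interpret it:

```sh
capfuse simulate --seed 7 --scenario c_d_reciprocal --out sim
capfuse call --fastq1 sim/reads_1.fastq --fastq2 sim/reads_2.fastq \
             --ref sim/reference.fa --targets sim/targets.bed --out call
capfuse interpret --junctions call/junctions.tsv --primary-pair chrA,chrB
```

which prints

```
wrote 3634 read pairs and truth for 2 junction(s) to sim
called 2 junction(s)
{
  "sample": [
    {
      "event_class": "two_way_reciprocal",
      "partners": [],
      "n_junctions": 2
    }
  ]
}
```

`call/junctions.tsv` holds the two junctions at exact truth coordinates
(compare `sim/truth.json`), each with its microhomology length, split
and pair support; `call/junctions.vcf` holds the same junctions as
paired VCF 4.2 BND records. `capfuse export-mrd` then emits the fused
breakpoint ± 300 bp flanks as FASTA plus a TSV manifest — the
patient-specific MRD target sequences.

Cohort statistics over the packaged 26-patient tables:

```sh
capfuse cohort
```

reports the orientation-type census `{"a": 0, "b": 1, "c": 23, "d": 16}`
(13 patients carry both c and d), the five three-way patients with
partner chromosomes 5, 5, 6, 8 and 15, the 181 kbp capture target, mean
age 5.1 years (20 boys, 6 girls, 4 relapses), a log-rank p-value of
3.1e-05 for relapse-free survival of three-way versus two-way patients,
and the exact hypergeometric association p = 5/14950 ≈ 3.3e-04 — all
four relapses fell in the five-patient three-way group, marking the
three-way translocation as a candidate relapse risk factor.

## Library use

```python
from capfuse import (Breakend, Junction, classify_type, build_derivative,
                     call_sample, SvCallingParams)
from capfuse.simulate import preset_scenario

j = Junction(Breakend("chr12", 12_023_837, "F"),
             Breakend("chr21", 36_315_905, "R"))
classify_type(j)            # 'c'

truth, reads, cfg = preset_scenario("three_way", seed=1)
callset = call_sample(truth.genome, SvCallingParams(), fastq_pairs=reads)
len(callset.junctions)      # 3
```

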