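# Methods

## Problem and model

A non-reference MGE insertion leaves three footprints in paired-end
alignments against the pre-insertion reference: (i) reads spanning a
junction align partially and carry the insert's edge as a soft clip;
(ii) mates sequenced from inside the insert fail to map while their
partners anchor next to the junction; (iii) pairs wholly inside the
insert map nowhere. `mgescout` treats these as complementary evidence:
clips give base-pair-precise breakpoints, anchored unmapped mates carry
enough sequence to identify the element by homology, and the pooled
unmapped reads carry enough to assemble the insertion outright.

Because integration typically duplicates a short target site (TSD), the
two junctions do not coincide: the upstream (right-clip) pileup sits at
the end of the duplicated site and the downstream (left-clip) pileup at
its start. The caller therefore reports an interval rather than a point;
its width estimates the TSD (here 2–9 bp) and must stay below the
25 bp vicinity bound.

## Parameters

All thresholds are fields of `PipelineConfig` with these defaults:

| parameter | default | meaning |
|---|---|---|
| `min_clip_length` | 5 bp | clips must be strictly longer to count as S |
| `max_insert` | 500 bp | distant-pair rescue threshold (outermost span) |
| `min_support_fraction` | 0.10 | clip support vs. local coverage (±100 bp mean) |
| `clip_quality_threshold` | 59 | mean clipped-base quality, ASCII phred+33 scale |
| `min_profile_length` / `min_profile_similarity` | 10 bp / 0.95 | clip-profile agreement next to the junction |
| `polya_fraction` | 0.8 | A- or T-dominance that bypasses the profile filter |
| `het_min_ratio` / `hom_min_ratio` | 0.10 / 0.90 | zygosity-ratio thresholds |
| `max_vicinity` | 25 bp | maximum breakpoint interval (TSD bound) |
| `repeat_flank` / `depth_imbalance` | 50 bp / 3.0 | repeat/deletion-edge rejection |
| `min_identity` / `min_length_fraction` | 0.90 / 0.70 | homology-hit filters |
| `support_window` | 500 bp | anchor-to-breakpoint distance (insert size) |
| `kmer_size` / `min_contig_length` | 51 / 500 bp | assembly |
| `max_alignments_per_read` / `min_read_support` | 5 / 2 | contig assignment |
| trim scores | 1 / −3 / −5 / −2 | match / substitution / gap open / gap extension |
| `accept_fraction` | 0.75 | trim score vs. longest clip length |
| `tolerance` | 20 bp | breakpoint matching in evaluation |

Notes on the less obvious choices:

* **Clip quality "59".** A phred score of 59 exceeds what Illumina
  encodings produce, so the threshold is interpreted on the ASCII
  (phred+33) scale: > 59 is equivalent to phred > 26. `clip_quality_mode`
  exposes both readings.
* **Zygosity ratio.** Defined as insertion-supporting reads over covering
  reads at the clip coordinate. Both junction pileups carry the
  insertion haplotype, so opposite-side clips within the vicinity are
  pooled into the numerator; without pooling a homozygous insertion
  plateaus near 0.5 and the 0.90 homozygous mode would be unusable.
  Default calling is heterozygous-sensitive (0.10).
* **Repeat/indel rejection.** A candidate is discarded when any of:
  its clip consensus matches the reference within 5% edit distance
  anywhere on the far side of the junction (a window of clip length +
  50 bp — this single windowed scan also catches matches shifted by a
  short indel, which is the short-indel artefact signature); or mean
  depth on the two 50 bp flanks differs more than 3-fold while the
  deeper flank has ≥ 5x (a long-deletion edge). The flank window and
  3-fold factor are package defaults, configurable.
* **Rescue ties.** When a distant pair's mates have equal mapping
  quality, the mate with the longer aligned length anchors; if still
  tied, mate 1. Inter-chromosomal pairs always rescue.

## Alignment engine

The scoring core is an affine-gap Smith–Waterman (numba-compiled, full
traceback; a gap of length L costs open + (L−1)·extend). Library searches
seed with exact 11-mers, pool seed diagonals into subject windows and run
the full DP only inside the window; identity is matches over alignment
columns. Two engineering guards keep the search near-linear without
changing results on real queries: seed k-mers occurring at more than 32
library positions are masked (homopolymer tails otherwise seed every
retrotransposon entry), and only the four subjects with the most seeds
are extended (a true homolog dominates the seed tally). Equivalence with
an exhaustive aligner is asserted in the test suite
(`Bio.Align.PairwiseAligner` as the independent oracle). Read-to-contig
assignment uses exact 21-mer candidate lookup verified by edit distance
(edlib), a screening step that never decides scores.

## Assembler

The internal assembler builds a k = 51 k-mer multiset from the collected
reads and their reverse complements and walks maximal paths greedily from
high-count seeds. k-mers observed once never start a contig; the walk
may cross one only when the branch rules favour it. At a branch the
dominant successor (≥ 4× any alternative) is taken outright; otherwise
the two strongest arms are probed 25 steps ahead and the arm carrying at
least twice the k-mer mass wins, else the walk stops. This design popped
the two failure modes observed with a strict drop-singletons unitig
compactor at 30x: recurrent sequencing errors (two reads sharing an
error) create short bubbles that would otherwise terminate every contig,
and Poisson coverage dips leave isolated single-copy true k-mers that
would otherwise split an insert into sub-500 bp fragments. Output is
deterministic for any read order (seeds ranked by count then k-mer;
contigs by length then sequence). Boundary trimming projects the
unaligned tips of a clip onto the contig so a sequencing error in the
clip's terminal base cannot shave boundary bases; with only one clipped
side, only that boundary is trimmed.

## Simulator

The generator reproduces the intended evaluation conditions: a uniform
ACGT reference with planted N blocks that insertions must avoid;
a four-family library (LINE 1200–2000 bp, SINE 520–800 bp, LTR
800–1500 bp, DNA 600–1200 bp, with 12–24 bp poly-A tails on LINE/SINE);
donor genomes with fragments ≥ 500 bp inserted at well-separated random
positions, each with a duplicated target site; 100 bp pairs with insert
length 400 ± 20, ~0.8% uniform substitution error (constant Q30, errored
bases Q10) at 30x or 90x; and a coordinate-sorted truth SAM placing each
read where a local aligner would: full matches in untouched sequence,
soft clips at junctions (a junction read needs ≥ 20 reference bases to
map), unmapped inside inserts with the mate preserved as anchor. SNV
divergence substitutes independent positions with a uniformly drawn base,
so a nominal 10% level yields ~7.5% realized divergence. Insertions are
homozygous by default; a diploid mode mixes donor and reference reads
50/50 to exercise the heterozygous zygosity path.

Two study designs are packaged: `simulation_set1_config` (four families
at 0% SNV, LINE/SINE/LTR at 10–50% SNV, random controls of
family-typical length; no TSD) and `simulation_set2_config` (exact
library copies, ~15%-diverged sister elements that are themselves
library entries — the cross-species situation — and novel random
fragments; TSD 2–9 bp).

**What the simulator does not model, and hence what passing tests do not
show:** real aligner behaviour (multi-mapping inside genomic repeat
families, mapping-quality noise, partial alignments of diverged reads to
reference element copies), indel sequencing errors, GC/coverage bias,
PCR duplicates and chimeras, and a repeat-rich reference background. On
real data these effects lower breakpoint recall and precision below the
near-perfect values reached here; in particular the 10%-divergence
stratum is recalled essentially completely on simulated data because
divergence lives in the donor, not in the read-to-donor alignment.

## Evaluation rules

Breakpoints match truth greedily, nearest first, one-to-one, when the
gap between the predicted interval and the true insertion coordinate is
≤ 20 bp (greedy matching is checked against an optimal-assignment oracle
in the tests). Type calls are scored with one reported type per
breakpoint — more than one type is a false positive — at element-family
level by default. A novel insertion counts as recovered only when its
breakpoint is found and the assembled, trimmed sequence matches the true
fragment within 2 bases at each end with ≥ 0.99 interior identity (the
interior-identity clause is this package's tightening of the
end-difference rule). Undefined ratios (0/0) are reported as undefined,
never as zero.

## Problem sizes

The acceptance script runs both designs on a 5 Mb single-chromosome
reference — the mixture design with 240 insertions at 30x and 90x, the
ladder design with 23 categories × 8 insertions at 30x — which keeps a
full from-scratch reproduction on one CPU in the minutes range while
leaving every per-category estimate based on dozens of events. The test
suite uses 2 Mb / 120-insert versions of the same designs plus smaller
fixtures.

## Known limitations

* The pipeline assumes local-alignment SAM input with soft clips present;
  end-to-end (global) alignments hide junction evidence.
* Breakpoints supported on a single side are retained (5′-truncated
  insertions), but their interval is a point and their trimming is
  one-ended.
* The internal assembler targets desk-scale insertion assembly; it does
  no scaffolding, gap filling or polishing, and genuinely ambiguous
  repeat junctions stop contigs rather than risk chimeras.
* Orientation-anomaly discordance (FF/RR pairs) is not used; rescue is
  distance/quality-based only.
* `--threads` is accepted for interface compatibility; the implementation
  is single-threaded and results never depend on it.
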