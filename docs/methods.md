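# Methods

This note documents the models, defaults, and numerical choices behind
`tdnakit`, and what its synthetic data can and cannot show about real
sequencing experiments.

## Problem setting and assumptions

The pipeline characterizes a *single-locus* integration event: zero, one,
or two copies of a transformation vector's T-DNA inserted at one host
position, possibly deleting a short stretch of host DNA at the junction.
It assumes paired-end short reads (default 100 bp) at moderate depth
(~29x), a haploid treatment of the host (a homozygous event or a pooled
sample is not distinguished from hemizygous), and a circular plasmid
reference whose T-DNA interval and functional elements are annotated.
Multi-locus insertions, internal T-DNA truncations or rearrangements, and
long-read data are out of scope.

The central difficulty addressed is *host homology*: constructs that carry
recipient-species DNA (native promoters, RNAi triggers against endogenous
genes) generate chimeric-looking read pairs from wild-type material. The
pipeline's answer is an exclusion blacklist derived from plasmid-host
homology search, applied to the **host-side** position of each chimeric
pair. Filtering on the plasmid side would be self-defeating whenever the
T-DNA terminus element is itself host-homologous — then every true junction
pair has a blacklisted plasmid end but a perfectly clean host position, and
host-side filtering keeps exactly the informative pairs while discarding
pairs whose host end lies within one insert size of a native homologous
locus.

## Stage parameters

| parameter | default | units | rationale |
|---|---|---|---|
| mapper seed `k` | 31 | bp | unique in ~10^18 random space; strided seeds retried at all offsets, then reseeded at k=13 for reads whose errors break every 31-mer |
| `max_mismatch_frac` | 0.1 | — | tolerates the 4% worst-cycle error with margin; reads over budget stay unmapped |
| homology `word_size` | 16 | bp | random 16-mer collisions between a 10 kb plasmid and a 10^5–10^9 bp host are pruned by `min_block_len` |
| homology `min_identity` / `min_block_len` | 0.9 / 50 | — / bp | a 100 bp read from a homologous element then always maps within a detected block |
| blacklist `margin` | 500 | bp | the library insert size: a homology-driven pair's host end lies within one insert of the block |
| `filter_side` | host | — | see above; `plasmid` and `both` are available |
| `cluster_window` | 500 | bp | physical scale of junction-spanning fragments |
| sporadic `min_abs` / `min_frac` | 3 / 0.1 | pairs / of D | a real junction is crossed by ~D·(insert−2·read)/(2·read) ≈ 0.75·D fragments per side; isolated pairs at 29x are noise |
| assembly `min_overlap` | 30 | bp | two 15-mer seeds; shorter overlaps are indistinguishable from chance at junction scale |
| assembly overlap identity | 0.90 | — | a suffix–prefix overlap always involves the high-error 3' tail of at least one read, so pairwise divergence reaches ~6–8% under the 0.1%→4% ramp; the polished contigs are then split-aligned at 0.95 |
| split `max_gap` | 25 | bp | a 1 bp indel between sample and reference splits a flank across two diagonals; the chain of clean segments may leave a small unexplained rim |
| backbone `min_depth_frac` / `min_span` | 0.3 / 200 | of D / bp | a real single-copy residue sits at ~1·D over its full length; sporadic hits stay sub-threshold |

## Junction calling and breakpoint conventions

Contigs are split-aligned to host and plasmid on seeded diagonals. Each
flank side is modelled as a *chain* of clean diagonal segments (windowed
match density ≥ 8/11, edges tightened to exact matches) anchored at a
contig end — robust to isolated indels inside a flank. The split point
maximizes total matched bases along the two junction-abutting diagonals and
is clamped to their clean regions; ties resolve toward the maximal host
extent. A contig fully explained end-to-end by a single host or plasmid
diagonal is not a junction (pure flank, pure insert, or a homologous
element) and yields no call.

The reported locus is the 1-based coordinate of the last retained host base
on the 5' flank; `deletion = R − L` where `L` is the exclusive end of the
retained prefix and `R` the first retained base of the 3' flank. With only
one flank recovered the deletion is reported missing, never zero.

**Micro-homology caveat.** An insertion has no unique textual
representation when the junction-adjacent bases coincide with the insert or
plasmid context (each comparison collides with probability ~1/4 at random
sequence). At such sites "exact locus" is ill-posed for any tool. The
simulator's site picker (`pick_clean_site`) therefore rejection-samples
positions where all four junction-adjacent comparisons are distinct, making
the ground truth well-defined; `build_event_genome` accepts arbitrary sites
and only warns.

## Copy number

Both the raw depth-normalized difference and the single-copy-gene
calibrated form are computed; the calibrated form is the headline value
because it cancels depth and mapping-rate factors within each sample and
absorbs residual library bias. The pipeline-level estimate is the
*length-weighted* mean of calibrated values over annotated T-DNA elements
of ≥ 200 bp (equivalent to a single ADT over the cassette union); short
elements would otherwise dominate the sampling noise, which scales as
`1/sqrt(element length · depth)`. Negative calibrated values (wild-type
background exceeding the GM signal under noise) are clipped to zero with a
warning. Display rounding is two decimals, half-up. ddPCR copy number is
the replicate-mean ratio with sample (n−1) RSDs; droplet-level Poisson
correction is out of scope — inputs are instrument-quantified counts.

## The simulator: what it emulates, and what it does not

`simulate_reads` emulates an Illumina-like paired-end run: fragment starts
uniform, insert length Normal(500, 10) truncated to [2·read_len, genome];
per-cycle substitution probability linear from 0.1% (cycle 1) to 4% (cycle
100); 5% of reads replaced by uniform random bases (one end per draw, the
mate kept); at most one N per read (a read receives its N with probability
0.02 — the cap is the stated constraint, the rate is this package's
choice); base qualities written as the Phred transform of the ramp. Before
fragment sampling, a haplotype is derived from the reference at mutation
rate 10⁻³ with 10% indels (geometric extension 0.3, minimum 1 bp), so reads
carry internally consistent divergence from the mapping reference.

Not emulated: PCR duplicates, GC bias, optical artifacts, quality-score
miscalibration, adapter read-through, chimeric library artifacts, and
diploid heterozygosity. Passing tests therefore demonstrate correctness of
the pipeline's logic under a faithful error/insert model, not robustness to
every failure mode of real libraries; in particular real data may need
external trimming (the pipeline consumes trimmed, length-unified reads).

`make_references` builds the standard study set: a random host chromosome;
a 10 kb circular plasmid with an 8 kb T-DNA carrying gene-scale cassette
elements (0.6–2 kb), a 300 bp RNAi trigger copied from one host locus and
placed 40 bp inside the T-DNA 5' border, and a 400 bp native promoter
copied from two host loci into the cassette interior — mirroring constructs
whose termini are recipient DNA; a 600 bp backbone origin annotation; and a
4 kb single-copy host interval as the depth calibrator (gene-scale, because
its sampling noise is common to every element's calibrated value).
Homology loci, the calibrator, and the recommended insertion-site zone are
kept ≥ 2 kb apart.

## Determinism and degenerate inputs

Every stochastic step consumes a `numpy` Generator seeded explicitly; the
pipeline output is byte-identical given identical inputs and
configuration. Assembly is deterministic: the globally best overlap is
merged first, ties resolved by the lexicographically smallest merged
sequence. Degenerate cases: zero-copy events return the host unchanged; a
T-DNA spanning the whole plasmid gives an empty backbone and a trivially
clean verdict; an empty blacklist keeps all chimeric pairs; a missing
wild-type control sets the wild-type copy-number terms to zero with a
warning; junction contigs on conflicting chromosomes raise rather than
guess.

## Problem sizes used in the test and acceptance suites

The full-scale synthetic recovery uses a 200 kb host, 10 kb plasmid, and
29x coverage for both GM and wild-type samples (~60k read pairs total);
module-level end-to-end tests use a 60 kb host at the same depth, and the
multi-arrangement recovery tests reuse that host across six
event configurations. These sizes preserve the quantities that drive the
statistics — absolute depth, insert geometry, element lengths, homology
block sizes — while scaling only the amount of uninvolved host sequence, to
which junction discovery is insensitive (its only effect is the genome-wide
noise floor, which the sporadic filter already dominates).

## Known limitations

* Arrangement inference relies on the depth-based copy number; between 1.5
  and 2.5 estimated copies the rounded value decides, so heavily biased
  libraries could flip a call to `unresolved`.
* Junctions inside host repeats longer than the insert size are
  fundamentally unresolvable by this read length; members are flagged
  non-unique and the cluster is rejected as contradictory rather than
  mis-placed.
* The deletion length is exact only when both flanks assemble; single-flank
  events report locus and leave the deletion missing.
* Backbone residues are detected but not localized on the host side.
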