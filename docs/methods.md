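# Methods

## Model and assumptions

`ervmap` detects germ-line insertions of a known mobile element from
paired-end short reads by exploiting two signals in alignments against the
*unmodified* host reference and against the element LTR:

- **anchored pairs**: one mate maps to the LTR, the other to the host
  flank.  The flank mate's host placement marks the neighbourhood of an
  insertion.
- **junction reads**: reads crossing a host/element boundary align to the
  host with the element portion soft-clipped (and to the LTR with the host
  portion soft-clipped).  The clip boundary is base-precise.

The method assumes the element's LTR is known and distinctive enough for
the aligner to anchor pairs; the internal element sequence need not be
intact.  Insertions are treated as independent loci; nested or adjacent
(< 5 kb) insertions would be merged into one interval by design.

Insertion geometry: integration duplicates a short target site (TSD,
6 bp for the element family modelled here).  An insertion after host base
*p* with TSD length *t* produces the junction structure
`host[1..p+t] + element + host[p+1..]`, so left- and right-junction
breakpoints project to host coordinates *p + t* and *p* respectively —
exactly *t* apart.  The breakpoint caller uses this as its TSD test: two
supported positions separated by exactly the expected TSD length are one
integration.  We report each breakpoint as the 1-based host coordinate
immediately 5′ of the element on its side of the junction; this convention
is what makes the two junction coordinates of one insertion differ by
exactly the TSD length rather than *t* − 1.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `mq_min` | 20 | phred-scaled MQ | excludes multi-mapping placements (e.g. insertions inside interspersed repeats); "below 20" is excluded, 20 is kept |
| `rc_frac` | 0.25 | fraction of mean depth μX | a real heterozygous/homozygous insertion should attract read support commensurate with coverage; features below 0.25·μX are noise.  Ties are retained ("less than" excludes) |
| `cluster_gap` | 5000 | bp | exceeds the ~4.3-kb element length, so flank evidence from either end of one provirus falls in one interval; strict `< gap` chaining |
| `min_clip` | 20 | bases | minimum soft-clip length worth re-placing on the host; shorter clips are rarely unique |
| `tsd_expected` | 6 | bp | TSD length of the modelled element family |
| `proximity_dist` | 5000 | bp | transcript neighbourhood likely to include the promoter |
| `min_support` | 2 | reads | a breakpoint position seen in a single clip is discarded — the automated stand-in for manual curation of clip alignments; sequencing errors at a clip boundary shift single observations by ±1 bp |

Aligner internals (`k` = 11 exact seed, match +1 / mismatch −1, x-drop 5,
`min_score` 20, `min_identity` 0.9): chosen for ≥ 20-base queries searched
in small windows, where exact 11-mer seeding is near-lossless (a 20-mer
with one error still contains an exact 11-mer except in a narrow placement
band).  All are exposed as function arguments.

## Candidate recovery modes

`candidate_reads` supports two recovery modes.  The *anchored* mode
(pipeline default) recovers only LTR-unmapped reads whose mate is
LTR-mapped.  The *unanchored* mode recovers every LTR-unmapped read; it is
appropriate when the LTR SAM is an element-targeted extract (as deposited
LTR BAMs typically are), where "every unmapped read" already means "every
read from an element-linked pair".  Against a complete library alignment —
which is what the simulator's truth aligner emits — the unanchored mode
would recover essentially the whole library and merge the genome into one
feature, so the pipeline anchors by mate.  Pair membership is resolved by
read name.

## Mean depth

μX is computed as aligned reference-consuming bases (CIGAR M/D/N/=/X over
mapped primary reads) divided by genome length, with no MQ filter at this
stage.  Secondary and supplementary alignments are skipped at the reader.

## Ward clustering and distances

The presence/absence matrix is compared by Euclidean distance between
binary rows (the square root of the Hamming count; the metric is
config-exposed).  Ward's minimum variance clustering uses the
Lance–Williams update on squared distances with heights reported on the
distance scale — `scipy.cluster.hierarchy.linkage(method="ward")`, which
is identical to R `hclust`'s `ward.D2` (verified on a frozen fixture).
Ward trees are only defined up to tie-breaking: on tied inputs several
valid dendrograms exist whose *sum of squared merge heights* (twice the
total within-cluster sum of squares) is nevertheless invariant, and the
test suite compares implementations accordingly.  Chromosome-length
correlation uses Pearson's product-moment coefficient with the two-sided
t-distribution p-value; "interval density" is operationalised as interval
count per chromosome, with counts-per-Mb available via `per_mb=True`
(the appropriate choice depends on how density is defined, so both are
provided).

## The synthetic universe

Defaults (the study conditions of the test suite and acceptance script):
three 1-Mb uniform-random chromosomes; 20 insertions placed ≥ 20 kb apart
and ≥ 10 kb from chromosome ends; element = 287-bp random LTR + random
internal filler to 4302 bp + identical LTR copy, with U3/R/U5 partition
1–146/147–163/164–287; random orientation per insertion; TSD 6 bp; 100-bp
paired reads, insert 400 ± 50 bp, 30× depth, 0.2 % substitution errors.
Sizes were chosen so that a full two-library experiment runs in about a
minute on one CPU while every junction receives ≥ 10 informative reads.

The simulator doubles as the external aligner: because each read's origin
is known, it emits the SAM an ideal aligner would produce against the
original host (junction reads soft-clipped at the true boundary;
element-internal reads unmapped) and against the LTR (reads overlapping an
LTR copy by ≥ 20 bases mapped, minus-strand placements stored
reverse-complemented per SAM convention).  The same errored sequences
appear in both SAM views and the optional FASTQ pair.

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate about real data: repetitive host sequence and the
multi-mapping MQ spectrum (all truth placements carry MQ 60, so the MQ
filter is exercised only by unit fixtures); indel sequencing errors and
quality-score structure; PCR duplicates; diverged or truncated element
copies; heterozygous insertions (every implanted element is present on the
single simulated haplotype).  Real-data sensitivity/precision therefore
cannot be extrapolated from the simulator's perfect recovery.

## Numerical and convention choices

- Internal coordinates are 0-based half-open; SAM/GTF converted at the
  boundary; all displayed loci 1-based inclusive (`chrom:start-end`).
- Book-ended footprints (gap exactly 0) merge, matching mergeBed's
  default.
- Clip-placement ties among co-optimal hits break by (score, lowest
  reference position, plus strand); LTR realignment likewise.  Output is
  deterministic; pipeline reruns are byte-identical (the JSON report
  carries no timestamps).
- Degenerate inputs: empty SAM → zero sites and empty downstream tables
  with a warning; empty truth set → sensitivity reported as undefined
  (`None`), not 0; clusters of a single sample skip tree building.
- Frequency denominators count analysed genomes/lines, each once.
- No read deduplication is performed anywhere (none is part of the
  method); duplicate-heavy libraries should be deduplicated upstream.

## Known limitations

- Breakpoints for insertions present in the reference (reference-allele
  intervals) follow the element alignment itself rather than clip
  geometry; the caller reports whatever supported positions exist and
  flags non-TSD configurations instead of resolving them.
- Low-complexity clips can place ambiguously inside the window; the
  support filter mitigates but does not eliminate this.
- The interval/integration ratio is computed per sample group; with
  replicate libraries of one genome it is 1.0 by construction (each locus
  yields one interval per group), so the clustered fraction is only
  informative for cohorts of distinct genomes.
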