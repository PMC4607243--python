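# ervmap

Mapping endogenous-retrovirus (ERV) integration sites in host genomes from
paired-end resequencing data.

Endogenous retroviruses such as the avian EAV-HP family integrate into the
germ line and segregate like any other polymorphism.  Because an insertion
is thousands of bases of non-reference sequence, it leaves two tell-tale
footprints in short-read data aligned to the reference: read pairs whose
mates split between the element's long terminal repeat (LTR) and the host
flank, and reads that cross a host/element junction and come back
soft-clipped.  `ervmap` turns those footprints into integration sites,
cross-sample intervals, base-pair breakpoints and population summaries.

The package is aimed at anyone mapping a known mobile element (ERV, LTR
retrotransposon, or similar) across a panel of resequenced genomes with a
host reference and the element/LTR sequence in hand.

## Method

For each sample, with alignments of the library against the element LTR and
against the host genome (SAM from any aligner):

1. **Candidate recovery** — reads unmapped against the LTR whose mate is
   LTR-mapped are recovered; their host alignments mark insertion flanks.
2. **Filtering** — host placements with mapping quality MQ < 20 are
   excluded; overlapping (or book-ended) footprints are merged into
   features; features supported by a read count RC < 0.25·μX<sub>i</sub>
   (a quarter of the sample's genome-wide mean depth) are excluded.  The
   survivors are the sample's integration sites.
3. **Interval clustering** — sites from all samples with < 5 kb of
   intervening sequence chain into a single interval (the 5-kb rule exceeds
   the ~4.3-kb element length, so flank evidence from both ends of one
   provirus lands in one interval); isolated sites form singleton
   intervals.  Presence/absence of each interval per sample gives a binary
   matrix with interval frequency *f*.
4. **Breakpoints and TSDs** — reads of pairs overlapping an interval are
   realigned to the LTR with a seeded, ungapped local aligner (exact
   11-mer seeds, +1/−1 scoring, x-drop 5); soft-clips ≥ 20 bases carry
   host flank sequence and are placed back on the host reference within
   the interval ± 5 kb.  The clip/LTR boundary projects to a 1-based host
   breakpoint.  Two breakpoints exactly 6 bp apart are the two junctions
   of one insertion flanking its target-site duplication (TSD).
5. **LTR region coverage** — per-interval coverage fractions of the LTR's
   U3 (1–146), R (147–163) and U5 (164–287) regions.
6. **Comparative analysis** — Euclidean distances between binary presence
   rows (√Hamming), Ward minimum-variance clustering with Newick/edge-list
   export, Pearson correlation of per-chromosome interval counts against
   chromosome length, nearest-transcript proximity (within 5 kb), and the
   transcribed fraction of the genome.

A synthetic-data module generates the whole test universe — random
chromosomes, implanted LTR-flanked elements with 6-bp TSDs, paired-end
libraries with substitution errors, and truth alignments against both
references — so every stage runs and is validated without external data.

## Worked example

Simulate a small cohort and run the full pipeline:

```bash
cat > run.yaml <<EOF
simulate:
  chrom_lengths: [1000000, 1000000, 1000000]
  n_integrations: 20
  seed: 42
libraries: 2
EOF
ervmap run --config run.yaml --out-dir out/
```

The run writes per-sample `sites.*.bed`, cross-sample `clusters.bed` and
`matrix.tsv`, `breakpoints.tsv`, distance/tree/edge tables and a
`report.json` that ends with:

```json
"stages": {
  "cluster":    {"n_sites": 40, "n_clusters": 20},
  "breakpoint": {"n_called": 20, "n_tsd": 20},
  "detect":     {"sites_per_sample": {"lib1": 20, "lib2": 20}, ...}
}
```

meaning: each library independently detected all 20 implanted insertions,
the two libraries' 40 sites collapsed into the same 20 intervals, and every
interval received a breakpoint call with the expected 6-bp TSD.  A row of
`breakpoints.tsv` looks like

```
cluster_id          chrom  breakpoints    tsd_len  support  u3_frac r_frac u5_frac
chr1:18926-19803    chr1   19332,19338    6        34,39    1.0     1.0    1.0
```

the two breakpoints are the last host base before each junction; their 6-bp
separation is the target-site duplication, and unit U3/R/U5 fractions say
the LTR was fully tiled by interval-linked reads.

Individual stages are also available as `ervmap
{simulate|detect|cluster|breakpoint|ltrcov|compare|evaluate}`; see
`ervmap <cmd> --help`.

## Limitations

- SAM input only (optionally gzipped); no BAM/CRAM or random access.
- Duplicate reads are not removed; supply deduplicated alignments if PCR
  duplicates are a concern.
- The clip aligner searches only the interval ± 5 kb window — it is a
  windowed stand-in for a genome-wide BLAT search, appropriate because
  clips are anchored by their interval.
- See `docs/methods.md` for the model, parameter and design notes.
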