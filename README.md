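# cracflow

A tested, reusable pipeline for quantifying protein–RNA binding from CRAC
(UV cross-linking and analysis of cDNAs) sequencing libraries, aimed at the
question of where chromatin factors sit on nascent RNA polymerase II
transcripts relative to the polymerase itself. It covers every desk-side
stage of a CRAC experiment — linker demultiplexing, adapter/quality
trimming, PCR-duplicate collapse, random-tag genomic deduplication,
transcript-class assignment, spliced/unspliced junction statistics,
strand-specific RPM coverage, pseudocounted log2 enrichment against a
polymerase reference, feature-level reproducibility filtering, and TSS/pA
metagene analysis — and ships a synthetic-data generator with full ground
truth so the whole pipeline is testable end-to-end without any downloads.

## The quantities it computes

Reads carry a 5′ linker `[3-nt random tag][sample barcode]`; after
demultiplexing and trimming (adapter clip, 3′ quality < Q30 clip, minimum
17 nt, ≤ 3 uncalled bases), identical `(tag, sequence)` pairs are collapsed,
low-complexity reads (> 80 % one nucleotide) are removed, and aligned reads
sharing `(tag, chromosome, strand, 5′ coordinate)` are collapsed to one
cross-linking event.

For deduplicated reads the pipeline computes, per library:

- **class distribution** — hierarchical assignment to
  rRNA > tRNA > other-PolIII > snoRNA > snRNA > mRNA > SUT > CUT > XUT >
  Ty > IGS, then antisense/intergenic;
- **splice ratio** — EE/(EI+IE), the count of exon–exon junction reads over
  exon–intron plus intron–exon boundary reads (≥ 3 nt overhang); a ratio
  below 1 indicates binding to unspliced, nascent transcripts;
- **coverage** — per-base, strand-specific counts excluding reads on
  RNAPI/RNAPIII transcripts (rRNA, tRNA, other-PolIII) and the
  mitochondrial genome, normalized to reads per million (RPM) of the
  included library and averaged across replicates;
- **enrichment** — per-base `log2((protein + 5) / (reference + 5))` between
  RPM tracks, where the pseudocount of 5 keeps the ratio finite;
- **feature statistics** — per-feature exonic RPM totals, cross-replicate
  coefficient of variation (sample SD / mean) and RPKM; a feature is
  *selected* when CV < 0.5 and RPKM > 30 (both strict);
- **metagenes** — TSS- and pA-anchored per-transcript matrices, aggregate
  profiles (sum for absolute coverage, mean for per-base enrichment), 2D
  heat-map exports, and expression-matched transcript subsets built by
  greedy nearest-neighbour matching on reference signal over the first
  300 nt.

## Worked example

The packaged demo simulates a complete study — two "Set1-like" replicates
(TSS-peaked binding, 0 to +500 nt, with an 8-fold over-bound IGS ncRNA),
two "Set2-like" replicates (body binding, +150 nt to 150 nt before the pA
site), two uniform polymerase replicates as the enrichment reference, and
an untagged background library — and runs every stage:

```bash
cracflow run-all -c examples/demo_config.yaml -o demo_out
```

The stderr log ends with (seed 42):

```
[cracflow] junctions: group=set1, ratio=0.5778
[cracflow] junctions: group=set2, ratio=0.2981
[cracflow] junctions: group=pol2, ratio=0.1577
[cracflow] features: group=set1, selected=34, total=42
[cracflow] features: group=set2, selected=34, total=42
[cracflow] metagene: group=set1, abs_argmax=99
[cracflow] metagene: group=set2, abs_argmax=493
```

Splice ratios below 1 for every factor reflect predominantly unspliced
(nascent) RNA in the libraries. The absolute metagene of the Set1-like
factor peaks at +99 nt from the TSS, inside its true 0–500 nt binding
window; the Set2-like factor peaks at +493 nt, inside the transcript body.
34 of 42 annotated features pass the CV < 0.5 / RPKM > 30 filter at this
depth, and `demo_out/features/set1.scatter.tsv` shows the planted IGS
feature at log2 enrichment ≈ 2.6 against the polymerase reference while
unplanted features sit near 0. Every stage output (truth tables, collapsed
FASTQ, deduplicated SAM, class counts, bedGraph tracks, feature tables,
metagene profiles) lands under `demo_out/`; rerunning with the same config
and seed reproduces all TSV/bedGraph files byte-for-byte.

Stages can equally be run one at a time (`cracflow simulate`, `preprocess`,
`dedup`, `classify`, `junctions`, `coverage`, `enrich`, `features`,
`metagene`) against the same output directory, or driven from Python via
`cracflow.pipeline`.

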