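# Methods

## Scope and model

cracflow quantifies where an RNA-binding factor sits on RNA polymerase II
transcripts from single-end CRAC libraries. The measurement model is:

1. Each sequenced read derives from one RNA fragment cross-linked to the
   purified protein. Its 5′ linker carries a 3-nt random tag and a sample
   barcode, in that order, ahead of the insert; a 3′ sequencing adapter
   follows the insert when the insert is shorter than the read.
2. PCR produces identical copies of each unique cDNA; copies are removed
   twice — before alignment by collapsing identical `(tag, sequence)`
   pairs, and after alignment by collapsing reads with the same random tag
   whose 5′ ends map to the same genomic coordinate on the same strand
   (this second pass also catches copies that diverged by 3′ trimming).
3. A deduplicated read is one cross-linking event. Coverage adds 1 to every
   base of every aligned block on the read's strand; gapped (spliced)
   alignments leave the intron untouched.
4. Binding *beyond* transcription is measured as the per-base
   `log2((factor_RPM + c)/(reference_RPM + c))` against a total-polymerase
   CRAC reference, with pseudocount `c = 5` (in RPM units) keeping the
   ratio finite and shrinking low-coverage positions toward 0.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| tag length | 3 | nt | random tag (UMI) in the 5′ linker |
| max uncalled bases | 3 | nt | trim gate |
| 3′ quality threshold | 30 | Phred | trailing-base clip |
| min post-trim length | 17 | nt | trim gate |
| min adapter overlap | 3 | nt | suffix/prefix adapter match |
| low-complexity cutoff | 0.8 | fraction | drop iff one base strictly exceeds it |
| junction overhang | 3 | nt | aligned nt required on each side of a splice boundary |
| pseudocount | 5 | RPM | enrichment stabilizer |
| CV threshold | 0.5 | — | reproducibility filter (strict <) |
| RPKM threshold | 30 | — | abundance filter (strict >) |
| exclusion classes | rRNA, tRNA, other-PolIII (+ mito chromosomes) | — | removed from coverage and library size |
| TSS window | −100…+1500 | nt | metagene columns |
| pA window | −1500…+100 | nt | metagene columns |
| flank | 100 | nt | unmasked margin outside the transcript |
| match tolerance | 0.05 | log10 | expression matching |
| match window | 300 | nt | reference signal measured over [TSS, TSS+300) |

All are configurable through the pipeline config (`params:` block).

## Design choices in open territory

- **Adapter/quality trimming** implements the intent of the four stated
  thresholds (uncalled bases, 3′ quality, minimum length, minimum adapter
  overlap) as an exact suffix/prefix match followed by a 3′ quality scan;
  it is not a bit-compatible re-implementation of any particular trimming
  tool, and allows no mismatches in the adapter match (the generator emits
  error-free reads by default, so exactness is the more useful contract).
- **Barcode matching** is exact by default; an optional Hamming tolerance
  assigns to the unique nearest barcode and sends distance ties to the
  unassigned stream.
- **Filter order**: low-complexity filtering runs after trimming and before
  collapse (configurable, logged); the collapse then operates on the reads
  that can actually map.
- **Class priority** (rRNA > tRNA > other-PolIII > snoRNA > snRNA > mRNA >
  SUT > CUT > XUT > Ty > IGS) puts abundant contaminant classes first so a
  read nested in two annotations is attributed conservatively; it is fully
  configurable and recorded in outputs. Antisense is assigned only to
  reads opposite an mRNA by default (configurable set).
- **Deduplication representative** is the first-seen read; representatives
  are interchangeable for counting, and first-seen keeps the operation
  order-stable and idempotent.
- **Feature totals use exonic bases only**, matching the mature-coordinate
  framing of the metagene and avoiding intron dilution on spliced genes;
  CV uses the sample standard deviation (ddof = 1).
- **RPKM** divides per-replicate assigned read counts (same-strand ≥ 1 nt
  block overlap, class hierarchy above) by feature kilobases and included
  library size in millions, then averages replicates.
- **Enrichment pseudocount applies to RPM-normalized values**, and the
  relative metagene averages *per-base* enrichment (mean of log-ratios),
  not the enrichment of averaged profiles — at uneven coverage these
  differ, so the order is fixed and stated.
- **Expression matching** is greedy nearest-neighbour without replacement
  in log10 signal, anchored on the class with fewest eligible features,
  visited in descending signal (ties to the lowest feature id); a group is
  kept only when every class has an unused feature within tolerance. This
  is this package's definition of "expression-matched", stated as such.
- **Coordinates**: 0-based half-open internally; GFF3 is written 1-based
  inclusive, SAM 1-based, bedGraph 0-based half-open. On the − strand the
  5′ coordinate is the rightmost aligned base.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: a miniature
two-chromosome genome (~105 kb) carrying mRNAs (some with one intron ≥
30 nt), SUTs/CUTs/XUTs, snoRNAs, rRNA and tRNA (exclusion classes), a
Ty-like repeat and an IGS-like ncRNA, packed without overlap with
intergenic gaps of 80–300 nt; and per-sample libraries in which

- unique molecules are sampled per feature from a multinomial over
  expression weights, and positionally from a binding model: uniform over
  [TSS, +500) (**tss_peaked**, Set1-like), uniform over [+150, pA−150)
  (**body**, Set2-like), uniform over the whole transcript (**uniform**,
  polymerase baseline), or forced across the first splice junction
  (**junction**, for splice-ratio studies);
- intron-containing genes yield spliced molecules (sampled in mature
  coordinates and mapped back through the exon structure) with a
  configurable spliced fraction;
- each molecule gets a random tag and a truncated-geometric PCR copy count
  (p = 0.55, max 10 — a synthetic choice; duplication rates and depths are
  not stated experimental quantities);
- reads are `tag + barcode + insert + adapter`, truncated to the read
  length, all bases at Q40; insert lengths are uniform on 20–80 nt and the
  read length (100 nt) is chosen so the full insert is always sequenced,
  which keeps the preprocessing truth predictions exact;
- a background fraction (2 %) is drawn uniformly over *all* annotated
  transcripts (emulating the untagged-strain control, and exercising the
  rRNA/tRNA exclusion), and a small oligo(A) contaminant fraction (0.5 %)
  exercises the low-complexity filter.

Truth tables record every molecule's feature, genomic block(s), strand,
tag, duplicate count, spliced flag and junction type, plus derived totals
(emitted reads, predicted kept reads/unique after trimming and filtering —
computed by an independent in-module oracle, not the preprocessing code).
Truth alignments can be emitted as SAM, replacing the external aligner.

**What the generator does not model:** sequencing errors are off by
default (an optional uniform substitution rate exists, under which the
exact-count oracles no longer hold), cross-link-induced deletions and
mutations, realistic base composition, multi-mapping reads, overlapping or
antisense gene pairs, and gel size selection. Passing tests therefore
demonstrate correctness of the pipeline's accounting, geometry and
statistics under clean conditions — not robustness to alignment artifacts
or error-rich data.

## Numerical and degenerate-input conventions

- RPM normalization refuses a zero library; enrichment refuses a
  non-positive pseudocount; feature statistics refuse < 2 replicates and
  zero-length features.
- A feature with zero mean coverage gets CV = ∞ (fails the filter) rather
  than NaN.
- Splice ratios with EI + IE = 0 are NaN for that replicate and excluded
  from the replicate mean with a warning row.
- Metagene cells outside the chromosome or more than `flank` nt outside
  the transcript are masked, never errors; all-masked columns report NaN.
- Ties everywhere (class assignment, matching, heat-map ordering) break on
  the lexicographically smallest feature id, making every output
  deterministic for a fixed config and seed; per-sample seeds derive from
  the global seed by a fixed affine map.

## Problem sizes

The packaged demo and the acceptance script use 6 000 unique molecules per
library over the ~105 kb genome (~75 k emitted reads across 7 libraries),
which puts several hundred deduplicated reads on a typical feature —
enough for the planted-effect recoveries (binding windows, 8-fold
enrichment, spliced fractions) to sit well inside their statistical noise
while the whole study runs in seconds. The test suite additionally runs
20-seed metagene-shape recovery at 100 000 molecules per library.

## Known limitations

- Alignment itself is out of scope; the pipeline consumes SAM/BAM from any
  aligner (or the truth emitter). Multi-mapping reads are reduced to the
  primary alignment.
- The junction-overhang rule and the expression-matching algorithm are
  explicit definitions of this package, configurable, and not claims about
  any other implementation.
- Spliced simulation supports two-exon genes; the junction *counting*
  handles any number of introns.
- Feature selection counts from real deposited libraries depend on the
  genome, annotation and aligner used and are not reproduced here.
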