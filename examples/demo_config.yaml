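# Demo study: two Set1-like replicates (TSS-peaked), two Set2-like replicates
# (body-distributed), two polymerase-baseline replicates (the enrichment
# reference) and one untagged background library, over a synthetic two-
# chromosome genome.  Fully deterministic for a fixed seed.
seed: 42
params:
  match_tolerance: 0.2
simulate:
  chrom_lengths: {chrI: 60000, chrII: 45000}
samples:
  - {name: set1_1, barcode: ATCGA, group: set1, role: protein, model: tss_peaked,
     n_molecules: 6000, spliced_fraction: 0.2,
     weight_overrides: {IGS_001: 8.0}}
  - {name: set1_2, barcode: GCTAA, group: set1, role: protein, model: tss_peaked,
     n_molecules: 6000, spliced_fraction: 0.2,
     weight_overrides: {IGS_001: 8.0}}
  - {name: set2_1, barcode: CGGTT, group: set2, role: protein, model: body,
     n_molecules: 6000, spliced_fraction: 0.35}
  - {name: set2_2, barcode: TAACG, group: set2, role: protein, model: body,
     n_molecules: 6000, spliced_fraction: 0.35}
  - {name: pol2_1, barcode: AGGAC, group: pol2, role: reference, model: uniform,
     n_molecules: 6000, spliced_fraction: 0.25}
  - {name: pol2_2, barcode: TCCTG, group: pol2, role: reference, model: uniform,
     n_molecules: 6000, spliced_fraction: 0.25}
  - {name: untagged, barcode: GATCC, group: background, role: background,
     n_molecules: 1500}
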