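# lsrseq

Switch-junction calling and breakpoint analysis for IgH amplicon
sequencing. `lsrseq` assembles per-read recombination junctions between a
repetitive donor switch region and acceptor windows (e.g. 3' regulatory
region enhancer neighborhoods used as surrogate acceptor switch regions),
classifies their structure, deduplicates them into unique junctions, and
characterizes breakpoints against AID/APOBEC3 hotspot motifs and
G-quadruplex propensity with an exact random-break null. A synthetic-read
simulator with a truth table makes the whole pipeline testable offline.

## What it does

- **reference**: validated reference segments (donor / acceptor /
  intermediate roles), 0-based half-open coordinates; breaks are
  inter-base positions.
- **motifs**: AID hotspots (WRCY / RGYW), APOBEC3 sites (TC / GA),
  run-based G4 propensity scores with sliding-window tract calls, and a
  gapless dot-plot repeat survey (default 20 bp windows at >= 90%
  identity, direct + inverted).
- **align**: seed-and-extend local alignment (exact affine-gap
  Smith-Waterman numba kernel) with HSP-style splitting so
  junction-spanning reads yield one segment per flank; primer trimming.
- **junctions**: per-read junction assembly (direct and complex
  post-switch junctions through an intermediate switch remnant) and
  blunt / microhomology / insertion classification with a single
  canonical breakpoint convention (microhomology assigned to both flanks,
  breaks at the outer edges).
- **quantify**: deduplication on junction coordinates + inserted
  sequence, junctions-per-million-reads, multi-primer library merging,
  dilution-series response.
- **breakstats**: break-to-feature distances vs an *exact* enumerated
  random-break expectation, Mann-Whitney observed-vs-null comparison,
  structure summaries, chi-square structure comparison, breakpoint maps.
- **simulate**: switch-like reference fixtures and junction-bearing
  amplicon reads (structure mixtures, clone sizes, substitution errors,
  background reads, uniform or motif-targeted break placement) with
  canonical truth records.

## CLI

```sh
lsrseq simulate --seed 1 --out sim/              # FASTQ + truth + regions
lsrseq regions validate sim/regions.fasta sim/regions.yaml
lsrseq scan sim/regions.fasta sim/regions.yaml --repeats --out tracks/
lsrseq call sim/reads.fastq --regions sim/regions.fasta \
    --manifest sim/regions.yaml --out calls.tsv
lsrseq quant calls.tsv --total-reads 1000 --uniques-out uniques.tsv
lsrseq stats uniques.tsv --out stats.json
lsrseq end-to-end --seed 1 --out run/            # whole pipeline
```

Outputs are TSV tables with fixed column order, BED tracks (0-based
half-open, chrom = region id), and schema-versioned JSON. Identical
inputs and seed reproduce byte-identical artifacts.

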