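# dartpop

Population structure, genetic diversity and linkage-disequilibrium (LD)
analysis for dominant (presence/absence) marker panels of fully homozygous
lines, such as DArT-genotyped cereal breeding panels with a consensus
genetic map.

The pipeline covers:

- **structure** — simple-matching similarity and modified Rogers' distance
  (MRD) matrices, classical PCoA with per-axis percent variance, per-axis
  density summaries with a bimodality flag, and within-group relatedness
  histograms/means.
- **diversity** — allele frequencies, polymorphic information content
  (PIC = 1 − (p² + q²)), group × chromosome PIC summary tables, and
  sliding-window PIC profiles along chromosomes (default: 5 cM window at
  500 positions).
- **divergence** — per-locus genetic distance between two labelled
  subpopulations (|p₁ − p₂|, the single-locus MRD), its windowed scan along
  the map, and region flagging against a seeded label-permutation null.
- **ld** — pairwise r² (squared allele-frequency correlation) with exact
  Fisher tests, the population-specific significance threshold (95 %
  quantile of unlinked-pair r²), loess decay curves per genome, the LD
  extent (curve/threshold intersection), adjacent-marker LD, and windowed
  LD profiles along chromosomes.
- **synthetic_data** — a founder-mosaic simulator (Poisson crossovers along
  the map) that generates two-subpopulation panels with tunable
  relatedness, LD decay, planted divergence regions and missingness, plus
  machine-readable ground truth.

## Input formats

- genotype matrix: TSV/CSV (or .xlsx), lines in rows by default
  (`markers-in-rows` dialect available), calls in {0, 1} with configurable
  missing tokens (`NA`, `-`, empty, ...);
- genetic map: TSV/CSV with columns marker, linkage group, position (cM).
  Split groups such as `2R-1`/`2R-2` are distinct linkage groups; the
  genome letter (A/B/R) is derived from the group name;
- line groups: two-column file, line id → growth habit
  (winter/spring/facultative).

## CLI

```sh
dartpop simulate --preset paper-like --seed 1 --out-dir data/
dartpop structure  --genotypes g.tsv --map m.tsv --groups h.tsv --out-dir out/
dartpop diversity  --genotypes g.tsv --map m.tsv --groups h.tsv --out-dir out/
dartpop divergence --genotypes g.tsv --map m.tsv --groups h.tsv --out-dir out/
dartpop ld         --genotypes g.tsv --map m.tsv --groups h.tsv --out-dir out/
dartpop all        --genotypes g.tsv --map m.tsv --groups h.tsv --out-dir out/
```

Common knobs: `--window-cm` (default 5), `--n-positions` (default 500),
`--span` (loess span, default 0.33), `--quantile` (default 0.95), `--seed`.
Every output table (`<stage>.<name>.tsv`) starts with a commented header of
the resolved parameters; outputs are byte-identical across runs on the same
inputs.

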