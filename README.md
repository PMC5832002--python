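# circconsensus

Multi-method consensus analysis of circular RNAs (circRNAs) from RNA-seq
back-splice detector outputs.

## The problem

circRNAs are covalently closed RNA loops produced by back-splicing: a
downstream splice donor joins an upstream acceptor, so the junction-spanning
reads map to the genome in chiastic order. Several detectors find such
junctions from RNA-seq data (CIRCexplorer, CIRI, find_circ, testrealign),
but they disagree wildly — on the same libraries one tool can report five
times more junctions than the others, most of them tool-private noise —
and each writes a different tab-separated dialect in a different coordinate
convention. Benchmarks against RNase R treatment (which degrades linear but
not circular RNA) showed that junctions found by a single method lack
reliability, and that requiring agreement between at least two methods is
good practice.

`circconsensus` is the analysis engine that sits downstream of the
detectors. For bioinformaticians who have run two to four of the supported
tools per sample, it:

1. **harmonizes** the native outputs into one junction identity space — a
   circRNA is the exact triple (chrom, start, end) after per-dialect
   coordinate conversion (internal convention: 0-based half-open);
2. **selects the reliable set**: junctions detected by ≥ *m* methods and
   supported by ≥ *r* back-splice reads (defaults *m* = *r* = 2; the support
   statistic is the maximum over (sample, method) evidence, so correlated
   estimates of the same molecules are never summed);
3. **annotates** each junction against a GTF as exonic / intronic /
   intergenic from the positions of its two ends, with composite labels
   (e.g. `exonic|intergenic spanning gene`) when the arc jumps over nested
   genes;
4. **quantifies** circRNAs as back-splice reads per million mapped reads
   (RPM = count × 10⁶ / library size), computes replicate-free log₂ fold
   changes with a pseudocount, cumulative-expression summaries, and pairwise
   Spearman correlations ρ between each circRNA and its overlapping genes'
   FPKM;
5. **reports** the aggregate statistics (per-method counts, agreement
   histogram, category shares, per-sample counts, correlation summary) as
   TSV tables plus one HTML summary.

A first-class synthetic-data generator (`circconsensus.fixtures`) plants a
ground-truth circRNA set over a toy annotation and emits all four detector
dialects, the GTF and expression tables, so every stage is testable against
a known truth.

## Worked example

Generate a synthetic four-sample dataset (50 planted circRNAs, default
detector sensitivities and false-positive rates, which emulate the real
tools' heterogeneity — testrealign over-calls heavily) and run the pipeline:

```
circconsensus fixtures generate --out demo/fx --seed 4 --n-genes 40 --n-circrnas 50
circconsensus run -c demo/fx/config.toml     # config written as below
```

with `config.toml`:

```toml
[input]
metadata = "metadata.tsv"      # sample_id, method, path, total_mapped_reads, expression_path
annotation = "annotation.gtf"

[consensus]
min_methods = 2
min_reads = 2

[output]
dir = "../run"
```

The run directory then contains, among others, `stats/run_summary.tsv`:

```
n_samples        4
n_union          322
n_reliable       50
n_genes_with_circrna  27
```

322 junctions were reported by at least one detector, but only 50 — exactly
the planted set — pass the two-method/two-read consensus. `stats/per_method.tsv`
shows why the union is so inflated:

```
method        n_circrnas  pct_of_union
circexplorer  31          10.0
ciri          49          15.0
findcirc      56          17.0
testrealign   288         89.0
```

testrealign alone accounts for 89% of the union; its private calls all
vanish under the quorum because single-method junctions cannot reach
two-method agreement. `stats/categories.tsv` classifies the reliable set
(90% exonic here), and `stats/correlation_summary.tsv` reports the 46
computable circRNA/host-gene Spearman correlations (mean ρ = −0.04 on this
null fixture, where circRNA counts and gene FPKM are simulated
independently).

The same stages are available as library functions
(`parse_detector_output`, `harmonize_calls`, `select_reliable`,
`categorize_circrna`, `circrna_matrix`, `correlate`, `build_summary`) for
use outside the CLI. Detector dialect definitions live in
[docs/FORMATS.md](docs/FORMATS.md); the model and its choices are described
in [docs/methods.md](docs/methods.md).

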