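# Methods

## Junction identity and harmonization

A circRNA is identified by its back-splice genomic positions. Internally
every junction is the triple (chrom, start, end) in 0-based half-open
coordinates (BED-compatible); each detector dialect declares offsets that
map its native convention onto this one (CIRI is 1-based inclusive, the
other three already 0-based half-open — see `docs/FORMATS.md`). Matching
across methods and samples is **exact** on the converted triple. No ±1
slack window is applied: a systematic shift by one tool is a property of
its dialect and belongs in its `DialectSpec` offsets, where it is corrected
once, for every call, rather than absorbed by fuzzy matching that could
merge genuinely distinct junctions (alternative back-splice acceptors one
base apart do occur).

The junction key is strandless. Detector strand calls are unreliable and
occasionally conflict for the same junction; keying on strand would split
one junction's evidence into two records and corrupt the consensus counts.
The reported strand is the majority vote over the contributing calls, with
ties and unreported strands shown as `.`. Display identifiers
(`chrom:start-end:strand`) use 1-based inclusive coordinates, the
convention of genome browsers and published circRNA tables; the chromosome
string is passed through untouched, so `chr` prefixes appear iff the input
used them.

Read counts from repeated reports by the same (sample, method) are summed
(they are separate records of the same file); counts from *different*
methods are never summed anywhere in the pipeline — see support statistic
below.

## The reliable set

A junction is *reliable* when (a) at least `min_methods` distinct enabled
methods detected it and (b) its read support reaches `min_reads`. Defaults
are 2 and 2: method agreement removes tool-private false calls (the
dominant error mode — one tool can emit several times more junctions than
the rest), and the read threshold removes single-read noise. Both
conditions are evaluated conjunctively on the same evidence. Setting both
to 1 makes selection the identity (maximum sensitivity); requiring all
enabled methods is the most conservative setting.

The support statistic defaults to the **maximum** over (sample, method)
evidence entries. The four detectors quantify the same molecules from the
same library, so summing across methods would count each molecule up to
four times; the maximum is the most optimistic single estimate.
`sum_over_methods` (per-sample cross-method sum, best sample) and
`sum_over_samples` (per-method cross-sample sum, best method) are available
for sensitivity analysis. Method counting is pooled across samples by
default, matching dataset-wide reporting; `scope="per_sample"` instead
requires the quorum within at least one sample.

## Category annotation

Each junction end is a single base: the first base of the junction
(internal `start`) and the last base before the acceptor (internal
`end − 1`). An end inside ≥ 1 annotated exon is *exonic*; inside ≥ 1 gene
span but no exon, *intronic*; outside all genes, *intergenic*. The junction
label combines the two end classes: equal classes give the plain label,
mixed classes a `|`-joined composite (`exonic|intronic`,
`exonic|intergenic`). A gene whose span lies strictly inside the junction
without containing either end adds the `intergenic spanning gene`
component — the signature of an arc jumping over small nested genes
(pseudogenes, snRNAs) inside a host gene's intron. Associated genes are the
union of genes hit by either end plus the spanned genes.

Exon overlap is containment of the end base, not exact splice-site
equality: the classification is about where the ends fall, and requiring
exact exon boundaries would penalize detectors that report the junction a
few bases off annotated splice sites. Overlap is unstranded by default
(circRNAs are routinely annotated to genes on either strand; antisense host
assignments are real and wanted); `stranded=True` restricts to the
junction's strand. `intronic_any_end=True` switches the mixed
exonic/intronic case to plain `intronic` for users who read "ends outside
exons" as "any end".

The annotation index is two interval-tree layers (exons, gene spans) per
chromosome; tests verify it against an exhaustive linear scan.

## Expression

circRNA abundance is RPM: back-splice reads × 10⁶ / total mapped reads of
the sample. When several methods report the same (junction, sample), the
per-sample count is reduced by the same default as the support statistic
(`max`; `sum` and `mean` selectable). Gene abundance arrives as FPKM from
upstream linear quantification and is taken as-is.

Log₂ fold changes are computed without replicates as
log₂((a + p)/(b + p)) with pseudocount p = 1 RPM by default. Zeros are
common in back-splice counts even for genuinely expressed circRNAs, and
with no dispersion model available the pseudocount is the standard guard;
1 RPM shrinks low-abundance ratios toward zero without materially moving
values above a few RPM. The threshold counter reports values strictly
above/below ±t (default 1.5).

`cumulative_share` answers "how many top rows cover fraction f of a
sample's expression" by descending prefix sums, with a 10⁻⁹-relative
tolerance on the target so float accumulation cannot demand an extra row.

A circRNA/gene correlation is computed for each (reliable circRNA,
overlapping gene) pair that is *computable*: ≥ 3 shared samples (the
minimum for a non-degenerate rank correlation) and both vectors
non-constant. Spearman ρ uses average ranks for ties
(`scipy.stats.spearmanr`; tests cross-check a brute-force average-rank
oracle). Non-computable pairs are omitted and counted. Correlations are
descriptive — no p-values or multiple-testing correction, as with n = 4
samples significance would be meaningless.

## Report

Percentages are round-half-up via decimal arithmetic (`pct`), printed at
1 decimal for reliable-set shares and 0 decimals for per-method shares, and
always recomputed from the integer counts they summarize — the TSVs are the
authoritative surface, the HTML mirrors them. Rendering is deterministic
given the stats and version strings.

## Synthetic data generator

`fixtures.generate` emulates what four detector runs leave on disk, from a
planted truth. What it models:

* a toy genome: 60 non-overlapping genes by default over up to four
  chromosomes, 2–5 exons of 100–300 bp, introns of 200–800 bp, intergenic
  gaps of 5–15 kb;
* planted circRNAs (default 100) with category mix 90% exonic / 5%
  intronic / 5% intergenic, placed so that the generator's category label
  provably matches the annotation rules (the generator and the annotator
  are independent implementations, cross-validated in tests);
* true per-sample read counts from a negative binomial (mean 8,
  dispersion 2 — zero-inflated, as real back-splice counts are), with the
  best sample bumped to ≥ 2 reads so every planted circRNA is recoverable
  under the default read threshold;
* per-method detection as one Bernoulli per (circRNA, method) — a detector
  either finds a junction in the dataset or misses it everywhere; defaults
  (CIRCexplorer 0.60, CIRI 0.85, find_circ 0.85, testrealign 0.90) mirror
  the tools' observed sensitivity ordering;
* method-private false positives at intergenic loci, Poisson counts per
  method with defaults 0.10 / 0.20 / 0.25 / 5.0 spurious junctions per true
  one — testrealign's over-calling dominates the union, as observed on real
  data; `shared_fp=True` additionally plants correlated two-method errors
  to stress the consensus;
* per-sample gene expression tables (log-normal FPKM, ~10% silent genes)
  simulated independently of circRNA counts, so correlation analyses on
  fixtures have a null expectation of ρ ≈ 0.

Library size defaults to 10⁶ mapped reads per sample so RPM equals the raw
count, which keeps fixture arithmetic legible; it is a parameter.

What it does **not** model: read-level alignment artifacts, shared
(non-private) false positives between specific tool pairs, method-specific
count biases (all detectors report the true count when they detect),
RNase R enrichment, and correlated circRNA/host-gene expression. Passing
tests therefore demonstrate the correctness of the harmonization,
consensus, annotation and quantification logic under known truth — not the
field accuracy of any detector.

All sampling comes from one `numpy` generator seeded by `FixtureSpec.seed`;
emitted files contain integers and fixed-format floats, so a fixed seed
yields byte-identical trees across platforms.

## Pipeline and determinism

The CLI wires the stages sequentially; every stage is a pure function of
its inputs, so rerunning on unchanged inputs is byte-identical (tested),
and any concurrent schedule respecting the stage dependencies would produce
the same bytes. Configuration errors (missing fields, unknown methods,
upstream-aligner parameters that do not belong to this tool) exit with
code 2 before any work; stage failures exit 1 and keep partial outputs.

## Problem sizes used in the test and acceptance suites

Property suites run on randomized in-memory instances (200 instances for
the consensus properties) and generated fixtures of 40–250 genes;
end-to-end recovery uses 500 planted circRNAs × 4 methods × 4 samples.
These sizes give exhaustive-oracle coverage (linear scans, subset
enumeration, brute-force ranks) while the whole suite stays in the
seconds range.

## Known limitations

* Exact-match harmonization cannot reconcile a tool that is off by one base
  only *sometimes* (e.g. strand-dependent shifts); dialect offsets are
  global per tool.
* Categories describe the junction ends only; the internal exon/intron
  structure of the circle (and hence ciRNA vs exon–intron circRNA
  subtypes) is not inferred.
* The correlation module assumes the same sample identifiers in the circRNA
  and gene matrices; no batch or depth correction is applied beyond
  RPM/FPKM.
* With four samples, fold changes and correlations are descriptive
  screening statistics, not inference.
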