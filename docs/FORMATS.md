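# Canonical detector output dialects

The four supported back-splice detectors each write a tab-separated file in
their own dialect. This note fixes one canonical column layout per tool; the
parsers and the fixture writers in `circconsensus.io_formats` implement these
definitions bit-exactly and are mutual inverses. If a deployed tool version
drifts from these layouts (extra columns, shifted coordinates), adapt the
dialect here and/or its `DialectSpec` offsets — never the matching logic.

Coordinates are converted to the internal convention (0-based half-open,
BED-compatible) by per-method `DialectSpec` offsets:
`internal_start = start_native + start_offset`,
`internal_end = end_native + end_offset`. A systematic per-tool shift
(e.g. an off-by-one of one tool relative to the others) is configuration on
the `DialectSpec`, not code.

## ciri — 1-based inclusive, headered

Header line, then one row per junction:

```
circRNA_ID	chr	circRNA_start	circRNA_end	junction_reads	strand
chr1:1000|2000	chr1	1000	2000	5	+
```

Default offsets: `start_offset = -1`, `end_offset = 0` (1-based inclusive
`[1000, 2000]` becomes internal `[999, 2000)`).

## findcirc — BED6-like sites table, 0-based half-open, no header

```
chrom	start	end	name	n_reads	strand
```

Column 5 (`n_reads`) is the back-splice read count. Default offsets: `(0, 0)`.

## circexplorer — BED12-derived, 0-based half-open, no header

Standard BED12 columns 1–12 plus `readNumber` as column 13:

```
chrom	start	end	name	score	strand	thickStart	thickEnd	itemRgb	blockCount	blockSizes	blockStarts	readNumber
```

Only columns 1–3, 6 and 13 are interpreted; the writer fills the rest with
single-block placeholders. Default offsets: `(0, 0)`.

## testrealign — splice-event table, 0-based half-open, no header

BED6-like rows whose name field carries a splits tag:

```
chrom	start	end	splits:<reads>:<total>:<type>:P	score	strand
```

`<type>` is `C` for a circular (back-splice) event; rows with any other type
are linear splice events reported in the same file and are *skipped*, not
treated as malformed. `<reads>` is the back-splice read count. Default
offsets: `(0, 0)`.

## Strand

`+`, `-`, or `.` for unreported/unknown, in every dialect.

## Malformed lines

Any line that does not conform to its dialect (wrong column count,
non-integer coordinates or counts, negative values, bad strand) raises a
parse error naming the file and line number. Lenient mode (`lenient=True` /
`--lenient`) downgrades these to warnings and skips the line; silent
coercion never happens, because silently dropped or mangled records corrupt
the downstream consensus counts.

## Other formats

* **GTF** — Ensembl flavour, 1-based inclusive; exon features must carry
  `gene_id` (and `gene_name` when available). Exons are deduplicated on
  (start, end) across transcripts of the same gene.
* **Gene expression table** — tab-separated with a header naming the gene id
  (`gene_id` or `tracking_id`), `FPKM`, and raw count (`raw_count` or
  `count`) columns; one row per gene, duplicates are errors.
* **Harmonized circRNA table** — TSV with header
  `circ_id  chrom  start  end  strand  evidence`; `start`/`end` internal
  0-based half-open, `circ_id` 1-based inclusive display form
  (`chrom:start-end:strand`), `evidence` a `;`-joined list of
  `sample:method:reads`. A BED6 companion (total reads in the score column)
  is written next to it.
* **truth.tsv** (fixtures) — one row per planted circRNA:
  `circ_id  chrom  start  end  strand  category  gene_id  methods
  count_<sample>...`; `methods` is the comma-joined set of detectors that
  reported the junction, `count_<sample>` the true per-sample back-splice
  read counts.
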