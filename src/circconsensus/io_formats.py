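"""Readers and writers for detector output dialects, GTF annotation and expression tables.

Four back-splice detectors are supported, each with its own tab-separated
output dialect and coordinate convention (see ``docs/FORMATS.md`` for the
canonical column definitions):

================  =========================  =========================
method            coordinate convention      read-count field
================  =========================  =========================
``circexplorer``  0-based half-open (BED12)  readNumber (column 13)
``ciri``          1-based inclusive          junction_reads (column 5)
``findcirc``      0-based half-open (BED6)   n_reads (column 5)
``testrealign``   0-based half-open (BED6)   splits tag in name field
================  =========================  =========================

Parsers return calls in each method's *native* convention; conversion to the
internal 0-based half-open convention happens in :mod:`circconsensus.harmonize`
via per-method :class:`DialectSpec` offsets, so systematic per-tool shifts are
configuration, not code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils

METHODS = ("circexplorer", "ciri", "findcirc", "testrealign")

STRANDS = ("+", "-", ".")  # "." encodes unknown


class ParseError(ValueError):
    """A malformed line in a detector/annotation/expression file."""


class ConfigurationError(ValueError):
    """An invalid method name or inconsistent configuration."""


@dataclass(frozen=True)
class BackspliceCall:
    """One back-splice junction reported by one method in one sample.

    Coordinates are kept in the reporting method's native convention;
    ``start_native <= end_native`` always holds after parsing.
    """

    method: str
    sample_id: str
    chrom: str
    start_native: int
    end_native: int
    strand: str
    read_count: int

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.start_native > self.end_native:
            raise ParseError(
                f"start {self.start_native} > end {self.end_native} for {self.chrom}"
            )
        if self.read_count < 0:
            raise ParseError(f"negative read count {self.read_count}")
        if self.strand not in STRANDS:
            raise ParseError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class DialectSpec:
    """Offsets converting a method's native coordinates to internal 0-based half-open.

    ``internal_start = start_native + start_offset`` and
    ``internal_end = end_native + end_offset``. An extra systematic per-tool
    shift (e.g. an off-by-one observed against other tools) is expressed by
    editing these offsets, never hard-coded elsewhere.
    """

    start_offset: int = 0
    end_offset: int = 0


#: Default conversion specs: CIRI prints 1-based inclusive coordinates, the
#: other three are already 0-based half-open.
DEFAULT_DIALECTS: dict[str, DialectSpec] = {
    "circexplorer": DialectSpec(0, 0),
    "ciri": DialectSpec(-1, 0),
    "findcirc": DialectSpec(0, 0),
    "testrealign": DialectSpec(0, 0),
}


@dataclass(frozen=True)
class GeneModel:
    """A gene with its (deduplicated) exons, internal 0-based half-open coordinates."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], max(e for _, e in self.exons)


@dataclass
class SampleExpression:
    """Per-sample gene expression: gene_id -> (fpkm, raw_count), plus library size."""

    sample_id: str
    genes: dict[str, tuple[float, int]]
    total_mapped_reads: int

    def __post_init__(self):
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")


# --------------------------------------------------------------------------
# detector dialect parsing
# --------------------------------------------------------------------------

def _fail(path, lineno, msg, lenient):
    full = f"{path}:{lineno}: {msg}"
    if lenient:
        warnings.warn(full)
        return None
    raise ParseError(full)


def _parse_int(s, what, path, lineno, lenient):
    try:
        v = int(s)
    except ValueError:
        return _fail(path, lineno, f"non-integer {what}: {s!r}", lenient)
    if v < 0:
        return _fail(path, lineno, f"negative {what}: {v}", lenient)
    return v


def _parse_ciri_line(fields, path, lineno, lenient):
    # circRNA_ID  chr  circRNA_start  circRNA_end  junction_reads  strand
    if len(fields) < 6:
        return _fail(path, lineno, f"expected 6 columns, got {len(fields)}", lenient)
    start = _parse_int(fields[2], "start", path, lineno, lenient)
    end = _parse_int(fields[3], "end", path, lineno, lenient)
    reads = _parse_int(fields[4], "junction_reads", path, lineno, lenient)
    if None in (start, end, reads):
        return None
    return fields[1], start, end, fields[5], reads


def _parse_findcirc_line(fields, path, lineno, lenient):
    # chrom  start  end  name  n_reads  strand
    if len(fields) < 6:
        return _fail(path, lineno, f"expected 6 columns, got {len(fields)}", lenient)
    start = _parse_int(fields[1], "start", path, lineno, lenient)
    end = _parse_int(fields[2], "end", path, lineno, lenient)
    reads = _parse_int(fields[4], "n_reads", path, lineno, lenient)
    if None in (start, end, reads):
        return None
    return fields[0], start, end, fields[5], reads


def _parse_circexplorer_line(fields, path, lineno, lenient):
    # BED12 + readNumber in column 13
    if len(fields) < 13:
        return _fail(path, lineno, f"expected 13 columns, got {len(fields)}", lenient)
    start = _parse_int(fields[1], "start", path, lineno, lenient)
    end = _parse_int(fields[2], "end", path, lineno, lenient)
    reads = _parse_int(fields[12], "readNumber", path, lineno, lenient)
    if None in (start, end, reads):
        return None
    return fields[0], start, end, fields[5], reads


def _parse_testrealign_line(fields, path, lineno, lenient):
    # chrom  start  end  name  score  strand; name = "splits:<reads>:<total>:<type>:P"
    # Only type "C" marks a circular (back-splice) event; other splice events
    # in the same file are skipped, signalled by the sentinel "LINEAR".
    if len(fields) < 6:
        return _fail(path, lineno, f"expected 6 columns, got {len(fields)}", lenient)
    name = fields[3].split(":")
    if len(name) != 5 or name[0] != "splits":
        return _fail(path, lineno, f"bad splits tag {fields[3]!r}", lenient)
    if name[3] != "C":
        return "LINEAR"
    start = _parse_int(fields[1], "start", path, lineno, lenient)
    end = _parse_int(fields[2], "end", path, lineno, lenient)
    reads = _parse_int(name[1], "splits reads", path, lineno, lenient)
    if None in (start, end, reads):
        return None
    return fields[0], start, end, fields[5], reads


_LINE_PARSERS = {
    "ciri": _parse_ciri_line,
    "findcirc": _parse_findcirc_line,
    "circexplorer": _parse_circexplorer_line,
    "testrealign": _parse_testrealign_line,
}

_HAS_HEADER = {"ciri": True, "findcirc": False, "circexplorer": False, "testrealign": False}

_CIRI_HEADER = "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\tjunction_reads\tstrand"


def parse_detector_output(
    path: str | Path, method: str, sample_id: str, lenient: bool = False
) -> list[BackspliceCall]:
    """Parse one detector output file into native-convention calls.

    Malformed lines raise :class:`ParseError` naming the line number;
    with ``lenient=True`` they are downgraded to warnings and skipped.
    An empty file yields an empty list.
    """
    if method not in METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; supported: {', '.join(METHODS)}"
        )
    line_parser = _LINE_PARSERS[method]
    calls: list[BackspliceCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and _HAS_HEADER[method]:
                continue
            parsed = line_parser(line.split("\t"), path, lineno, lenient)
            if parsed is None or parsed == "LINEAR":
                continue
            chrom, start, end, strand, reads = parsed
            if strand not in STRANDS:
                if _fail(path, lineno, f"bad strand {strand!r}", lenient) is None:
                    continue
            if start > end:
                if _fail(path, lineno, f"start {start} > end {end}", lenient) is None:
                    continue
            calls.append(
                BackspliceCall(method, sample_id, chrom, start, end, strand, reads)
            )
    return calls


# --------------------------------------------------------------------------
# detector dialect writers (exact inverses of the parsers, used by fixtures)
# --------------------------------------------------------------------------

def _ciri_row(c: BackspliceCall) -> str:
    cid = f"{c.chrom}:{c.start_native}|{c.end_native}"
    return f"{cid}\t{c.chrom}\t{c.start_native}\t{c.end_native}\t{c.read_count}\t{c.strand}"


def _findcirc_row(c: BackspliceCall) -> str:
    name = f"{c.chrom}_{c.start_native}_{c.end_native}"
    return f"{c.chrom}\t{c.start_native}\t{c.end_native}\t{name}\t{c.read_count}\t{c.strand}"


def _circexplorer_row(c: BackspliceCall) -> str:
    size = c.end_native - c.start_native
    return "\t".join(
        [
            c.chrom,
            str(c.start_native),
            str(c.end_native),
            "circular_RNA",
            "0",
            c.strand,
            str(c.start_native),
            str(c.end_native),
            "0,0,0",
            "1",
            f"{size},",
            "0,",
            str(c.read_count),
        ]
    )


def _testrealign_row(c: BackspliceCall) -> str:
    name = f"splits:{c.read_count}:{c.read_count}:C:P"
    return f"{c.chrom}\t{c.start_native}\t{c.end_native}\t{name}\t0\t{c.strand}"


_ROW_WRITERS = {
    "ciri": _ciri_row,
    "findcirc": _findcirc_row,
    "circexplorer": _circexplorer_row,
    "testrealign": _testrealign_row,
}


def write_detector_file(calls: Iterable[BackspliceCall], method: str, path: str | Path) -> None:
    """Write calls in ``method``'s native dialect; mutual inverse of the parser."""
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}")
    lines = []
    if _HAS_HEADER[method]:
        lines.append(_CIRI_HEADER)
    for c in calls:
        if c.method != method:
            raise ConfigurationError(
                f"call from method {c.method!r} passed to {method!r} writer"
            )
        lines.append(_ROW_WRITERS[method](c))
    Path(path).write_text("".join(l + "\n" for l in lines))


# --------------------------------------------------------------------------
# GTF
# --------------------------------------------------------------------------

def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse an Ensembl-flavour GTF into gene models.

    Exons are grouped by ``gene_id`` and deduplicated on (start, end) across
    transcripts; GTF 1-based inclusive coordinates become internal 0-based
    half-open, so feature lengths are preserved. A GTF with no exon features
    yields an empty list with a warning; an exon lacking ``gene_id`` is a
    parse error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    n_exons = 0
    for exon in db.features_of_type("exon"):
        n_exons += 1
        if "gene_id" not in exon.attributes:
            raise ParseError(f"{path}: exon at {exon.seqid}:{exon.start} lacks gene_id")
        gid = exon.attributes["gene_id"][0]
        gname = exon.attributes.get("gene_name", [gid])[0]
        rec = by_gene.setdefault(
            gid, {"name": gname, "chrom": exon.seqid, "strand": exon.strand, "exons": set()}
        )
        # GTF is 1-based inclusive: [start, end] -> internal [start-1, end)
        rec["exons"].add((exon.start - 1, exon.end))
    if n_exons == 0:
        warnings.warn(f"{path}: no exon features found")
        return []
    genes = []
    for gid, rec in by_gene.items():
        strand = rec["strand"] if rec["strand"] in ("+", "-") else "."
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=rec["name"],
                chrom=rec["chrom"],
                strand=strand,
                exons=tuple(sorted(rec["exons"])),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


# --------------------------------------------------------------------------
# expression tables
# --------------------------------------------------------------------------

_GENE_ID_ALIASES = ("gene_id", "tracking_id")
_FPKM_ALIASES = ("FPKM", "fpkm")
_COUNT_ALIASES = ("raw_count", "count", "raw_frags")


def _find_column(header: list[str], aliases: tuple[str, ...], path) -> int:
    for a in aliases:
        if a in header:
            return header.index(a)
    raise ParseError(f"{path}: none of columns {aliases} found in header {header}")


def parse_expression_table(path: str | Path, total_mapped_reads: int) -> SampleExpression:
    """Parse a Cufflinks-style gene expression table (gene id, FPKM, raw count).

    Duplicate gene ids and negative values are errors, never coerced.
    """
    sample_id = Path(path).stem
    genes: dict[str, tuple[float, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        gi = _find_column(header, _GENE_ID_ALIASES, path)
        fi = _find_column(header, _FPKM_ALIASES, path)
        ci = _find_column(header, _COUNT_ALIASES, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) <= max(gi, fi, ci):
                raise ParseError(f"{path}:{lineno}: too few columns")
            gid = fields[gi]
            try:
                fpkm = float(fields[fi])
                count = int(fields[ci])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
            if fpkm < 0 or count < 0:
                raise ParseError(f"{path}:{lineno}: negative expression value")
            if gid in genes:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            genes[gid] = (fpkm, count)
    return SampleExpression(sample_id=sample_id, genes=genes, total_mapped_reads=total_mapped_reads)


# --------------------------------------------------------------------------
# harmonized circRNA table + BED companion
# --------------------------------------------------------------------------

_CIRC_TABLE_HEADER = "circ_id\tchrom\tstart\tend\tstrand\tevidence"


def _format_evidence(evidence: dict) -> str:
    items = sorted(evidence.items())
    return ";".join(f"{s}:{m}:{n}" for (s, m), n in items)


def write_circrna_table(records, path: str | Path) -> None:
    """Write harmonized circRNAs as a TSV (plus a BED6 companion next to it).

    Coordinates in the ``start``/``end`` columns are internal 0-based
    half-open; the ``circ_id`` column carries the 1-based inclusive display
    identifier. The ``evidence`` column serializes the full
    (sample, method) -> read count map so that the table round-trips.
    """
    from .harmonize import circrna_id  # local import to avoid a cycle

    path = Path(path)
    rows = [_CIRC_TABLE_HEADER]
    bed_rows = []
    for c in records:
        cid = circrna_id(c)
        rows.append(
            f"{cid}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{_format_evidence(c.evidence)}"
        )
        total = sum(c.evidence.values())
        bed_rows.append(f"{c.chrom}\t{c.start}\t{c.end}\t{cid}\t{total}\t{c.strand}")
    path.write_text("".join(r + "\n" for r in rows))
    path.with_suffix(".bed").write_text("".join(r + "\n" for r in bed_rows))


def parse_circrna_table(path: str | Path):
    """Inverse of :func:`write_circrna_table` (TSV part)."""
    from .harmonize import CircRNA

    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _CIRC_TABLE_HEADER:
            raise ParseError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            _, chrom, start, end, strand, ev = fields
            evidence = {}
            if ev:
                for item in ev.split(";"):
                    s, m, n = item.rsplit(":", 2)
                    s, m = s, m
                    evidence[(s, m)] = int(n)
            records.append(
                CircRNA(chrom=chrom, start=int(start), end=int(end), strand=strand, evidence=evidence)
            )
    return records
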