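"""Convert native detector calls into a single back-splice identity space.

A circRNA is identified by its back-splice genomic positions. After each
method's native coordinates are shifted into the internal 0-based half-open
convention, calls agreeing exactly on (chrom, start, end) are the same
junction regardless of method, sample or reported strand; their evidence is
merged into one record. Matching is exact — systematic per-tool offsets are
handled by :class:`~circconsensus.io_formats.DialectSpec`, not by a slack
window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import (
    DEFAULT_DIALECTS,
    BackspliceCall,
    ConfigurationError,
    DialectSpec,
    ParseError,
)


@dataclass
class CircRNA:
    """A harmonized back-splice junction with per-(sample, method) read evidence.

    ``start``/``end`` are internal 0-based half-open. The junction key is
    strandless; ``strand`` is the majority strand over the contributing calls
    ("." when tied or unreported).
    """

    chrom: str
    start: int
    end: int
    strand: str
    evidence: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def methods(self) -> set[str]:
        return {m for (_, m) in self.evidence}

    def samples(self) -> set[str]:
        return {s for (s, _) in self.evidence}

    def total_reads(self) -> int:
        return sum(self.evidence.values())


def harmonize_calls(
    calls: list[BackspliceCall],
    dialects: dict[str, DialectSpec] | None = None,
) -> list[CircRNA]:
    """Merge native calls into harmonized circRNAs keyed on exact junction position.

    Read counts from repeated reports of the same junction by the same
    (sample, method) are summed; the output is sorted by (chrom, start, end).
    Total read evidence is conserved.
    """
    if dialects is None:
        dialects = DEFAULT_DIALECTS
    merged: dict[tuple[str, int, int], CircRNA] = {}
    strand_votes: dict[tuple[str, int, int], Counter] = {}
    for call in calls:
        try:
            spec = dialects[call.method]
        except KeyError:
            raise ConfigurationError(f"no dialect spec for method {call.method!r}") from None
        start = call.start_native + spec.start_offset
        end = call.end_native + spec.end_offset
        if start >= end:
            raise ParseError(
                f"degenerate junction {call.chrom}:{start}-{end} from {call.method}"
            )
        key = (call.chrom, start, end)
        rec = merged.get(key)
        if rec is None:
            rec = CircRNA(chrom=call.chrom, start=start, end=end, strand=".")
            merged[key] = rec
            strand_votes[key] = Counter()
        ev_key = (call.sample_id, call.method)
        rec.evidence[ev_key] = rec.evidence.get(ev_key, 0) + call.read_count
        if call.strand in ("+", "-"):
            strand_votes[key][call.strand] += 1
    out = []
    for key in sorted(merged):
        rec = merged[key]
        votes = strand_votes[key]
        if votes and votes["+"] != votes["-"]:
            rec.strand = "+" if votes["+"] > votes["-"] else "-"
        else:
            rec.strand = "."
        # zero-read reports carry no evidence; drop the empty entries
        rec.evidence = {k: v for k, v in rec.evidence.items() if v > 0}
        out.append(rec)
    return [c for c in out if c.evidence]


def circrna_id(c: CircRNA) -> str:
    """Display identifier ``chrom:start-end:strand`` with 1-based inclusive coordinates.

    The chromosome name is passed through untouched: a "chr" prefix is
    printed iff the input annotation used one.
    """
    return f"{c.chrom}:{c.start + 1}-{c.end}:{c.strand}"


def parse_circrna_id(cid: str) -> tuple[str, int, int, str]:
    """Inverse of :func:`circrna_id`: returns (chrom, start, end, strand) internally keyed."""
    body, _, strand = cid.rpartition(":")
    chrom, _, span = body.rpartition(":")
    first, _, last = span.partition("-")
    if not chrom or strand not in ("+", "-", "."):
        raise ValueError(f"malformed circRNA id {cid!r}")
    return chrom, int(first) - 1, int(last), strand
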