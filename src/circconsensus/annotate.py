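"""Classify circRNAs against gene annotation: exonic, intronic, intergenic.

Each back-splice end is a single genomic base (the first base of the
junction and the last base before the acceptor, i.e. internal ``start`` and
``end - 1``). An end falling inside at least one annotated exon is exonic;
inside a gene body but no exon, intronic; outside all genes, intergenic.
The junction category combines the two end classes; a gene lying strictly
inside the junction span without containing either end adds the
"intergenic spanning gene" qualifier seen when a circRNA's arc jumps over
small nested genes (typically pseudogenes or snRNAs inside host introns).

Overlap is unstranded by default: circRNAs are frequently annotated to genes
on either strand, and detector strand calls are unreliable for some tools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from intervaltree import IntervalTree

from .harmonize import CircRNA, circrna_id
from .io_formats import GeneModel

#: Category vocabulary, in display/join order.
_CATEGORY_RANK = {"exonic": 0, "intronic": 1, "intergenic": 2, "intergenic spanning gene": 3}


@dataclass
class ExonIndex:
    """Interval-queryable view of a gene annotation.

    Two stabbing layers per chromosome: exon intervals and whole gene spans,
    each mapping to gene ids. Gene spans always contain their exons, so an
    exon hit implies a span hit for the same gene.
    """

    exons: dict[str, IntervalTree]
    spans: dict[str, IntervalTree]
    gene_names: dict[str, str]
    gene_strands: dict[str, str]


def build_exon_index(genes: list[GeneModel]) -> ExonIndex:
    exons: dict[str, IntervalTree] = {}
    spans: dict[str, IntervalTree] = {}
    names: dict[str, str] = {}
    strands: dict[str, str] = {}
    for g in genes:
        names[g.gene_id] = g.gene_name
        strands[g.gene_id] = g.strand
        etree = exons.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            etree.addi(s, e, g.gene_id)
        s0, e0 = g.span
        spans.setdefault(g.chrom, IntervalTree()).addi(s0, e0, g.gene_id)
    return ExonIndex(exons=exons, spans=spans, gene_names=names, gene_strands=strands)


def _stab(trees: dict[str, IntervalTree], chrom: str, pos: int) -> set[str]:
    tree = trees.get(chrom)
    if tree is None:
        return set()
    return {iv.data for iv in tree.at(pos)}


def classify_end(
    position: tuple[str, int], idx: ExonIndex, strand: str | None = None
) -> tuple[str, set[str]]:
    """Classify one junction end base; returns (class, genes hit).

    With ``strand`` given, only genes on that strand are considered.
    """
    chrom, pos = position
    exon_genes = _stab(idx.exons, chrom, pos)
    span_genes = _stab(idx.spans, chrom, pos)
    if strand in ("+", "-"):
        exon_genes = {g for g in exon_genes if idx.gene_strands.get(g) == strand}
        span_genes = {g for g in span_genes if idx.gene_strands.get(g) == strand}
    if exon_genes:
        return "exonic", exon_genes
    if span_genes:
        return "intronic", span_genes
    return "intergenic", set()


@dataclass
class CircAnnotation:
    """Category label and associated genes for one circRNA."""

    circrna_id: str
    category: str
    genes: tuple[str, ...]
    gene_names: tuple[str, ...]
    spanned_genes: tuple[str, ...] = ()


def _spanned_genes(c: CircRNA, idx: ExonIndex, end_genes: set[str]) -> set[str]:
    """Genes whose span lies strictly inside the junction without containing either end base."""
    tree = idx.spans.get(c.chrom)
    if tree is None:
        return set()
    spanned = set()
    for iv in tree.overlap(c.start, c.end):
        if iv.data in end_genes:
            continue
        if iv.begin >= c.start and iv.end <= c.end:
            # strictly inside: neither end base (c.start, c.end - 1) is covered
            if not (iv.begin <= c.start < iv.end) and not (iv.begin <= c.end - 1 < iv.end):
                spanned.add(iv.data)
    return spanned


def categorize_circrna(
    c: CircRNA,
    idx: ExonIndex,
    stranded: bool = False,
    intronic_any_end: bool = False,
) -> CircAnnotation:
    """Assign a category label combining both back-splice end classes.

    Both ends exonic -> "exonic"; both ends inside genes but outside exons ->
    "intronic"; both ends outside genes -> "intergenic". Mixed end classes
    produce a "|"-joined composite. ``intronic_any_end=True`` instead calls a
    junction intronic as soon as one end is intronic while both ends are
    genic. Genes fully spanned by the junction without containing its ends
    add the "intergenic spanning gene" component.
    """
    strand = c.strand if (stranded and c.strand in ("+", "-")) else None
    cls_start, genes_start = classify_end((c.chrom, c.start), idx, strand)
    cls_end, genes_end = classify_end((c.chrom, c.end - 1), idx, strand)
    end_genes = genes_start | genes_end
    components = {cls_start, cls_end}
    if intronic_any_end and components == {"exonic", "intronic"}:
        components = {"intronic"}
    spanned = _spanned_genes(c, idx, end_genes)
    if strand is not None:
        spanned = {g for g in spanned if idx.gene_strands.get(g) == strand}
    if spanned:
        if components == {"intergenic"}:
            # both ends intergenic and a gene inside the arc: the qualifier
            # subsumes the plain label
            components = set()
        components.add("intergenic spanning gene")
    category = "|".join(sorted(components, key=_CATEGORY_RANK.__getitem__))
    all_genes = tuple(sorted(end_genes | spanned))
    return CircAnnotation(
        circrna_id=circrna_id(c),
        category=category,
        genes=all_genes,
        gene_names=tuple(idx.gene_names.get(g, g) for g in all_genes),
        spanned_genes=tuple(sorted(spanned)),
    )


def circrnas_per_gene(
    annotations: list[CircAnnotation],
) -> tuple[dict[str, int], dict[int, int]]:
    """Per-gene circRNA counts and their frequency distribution.

    A circRNA overlapping several genes increments each; genes without any
    circRNA do not appear.
    """
    per_gene: Counter = Counter()
    for a in annotations:
        for g in a.genes:
            per_gene[g] += 1
    distribution: Counter = Counter(per_gene.values())
    return dict(per_gene), dict(distribution)
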