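"""Category classification against gene annotation, checked versus linear-scan oracles."""

import random

from circconsensus.annotate import (
    build_exon_index,
    categorize_circrna,
    circrnas_per_gene,
    classify_end,
)
from circconsensus.harmonize import CircRNA
from circconsensus.io_formats import GeneModel


def _gene(gid, chrom, strand, exons, name=None):
    return GeneModel(gid, name or gid, chrom, strand, tuple(exons))


THREE_GENES = [
    _gene("A", "1", "+", [(100, 200), (400, 500), (800, 900)]),
    _gene("B", "1", "-", [(2000, 2100), (2500, 2600)]),
    _gene("C", "2", "+", [(50, 150)]),
]


def _oracle_classify(genes, chrom, pos, strand=None):
    """Exhaustive linear scan over all exons and gene spans."""
    exonic, genic = set(), set()
    for g in genes:
        if g.chrom != chrom or (strand and g.strand != strand):
            continue
        s0, e0 = g.span
        if s0 <= pos < e0:
            genic.add(g.gene_id)
        for s, e in g.exons:
            if s <= pos < e:
                exonic.add(g.gene_id)
    if exonic:
        return "exonic", exonic
    if genic:
        return "intronic", genic
    return "intergenic", set()


def _oracle_categorize(genes, c):
    """Independent reimplementation of the junction category rules."""
    cls1, g1 = _oracle_classify(genes, c.chrom, c.start)
    cls2, g2 = _oracle_classify(genes, c.chrom, c.end - 1)
    spanned = set()
    for g in genes:
        if g.chrom != c.chrom or g.gene_id in (g1 | g2):
            continue
        s0, e0 = g.span
        if (
            s0 >= c.start
            and e0 <= c.end
            and not (s0 <= c.start < e0)
            and not (s0 <= c.end - 1 < e0)
        ):
            spanned.add(g.gene_id)
    parts = {cls1, cls2}
    if spanned:
        if parts == {"intergenic"}:
            parts = set()
        parts.add("intergenic spanning gene")
    order = ["exonic", "intronic", "intergenic", "intergenic spanning gene"]
    return "|".join(sorted(parts, key=order.index)), g1 | g2 | spanned


def test_classify_end_basic_cases():
    idx = build_exon_index(THREE_GENES)
    assert classify_end(("1", 150), idx) == ("exonic", {"A"})
    assert classify_end(("1", 300), idx) == ("intronic", {"A"})
    assert classify_end(("1", 1500), idx) == ("intergenic", set())
    assert classify_end(("3", 10), idx) == ("intergenic", set())  # unknown chrom


def test_empty_annotation_returns_empty_everywhere():
    idx = build_exon_index([])
    assert classify_end(("1", 100), idx) == ("intergenic", set())


def test_antisense_overlapping_genes_both_reported():
    genes = [
        _gene("F", "1", "+", [(100, 300), (900, 1000)]),
        _gene("R", "1", "-", [(150, 250), (850, 950)]),
    ]
    idx = build_exon_index(genes)
    cls, hit = classify_end(("1", 400), idx)  # intron of both
    assert (cls, hit) == ("intronic", {"F", "R"})
    # stranded mode restricts to one
    assert classify_end(("1", 400), idx, strand="-") == ("intronic", {"R"})


def test_classify_end_agrees_with_linear_scan_on_random_annotations():
    rng = random.Random(9)
    for _ in range(20):
        genes = []
        for i in range(rng.randint(1, 12)):
            chrom = rng.choice(["1", "2"])
            start = rng.randrange(0, 5000)
            exons = []
            pos = start
            for _ in range(rng.randint(1, 4)):
                pos += rng.randint(0, 300)
                exons.append((pos, pos + rng.randint(50, 200)))
                pos = exons[-1][1]
            genes.append(_gene(f"g{i}", chrom, rng.choice("+-"), exons))
        idx = build_exon_index(genes)
        for _ in range(100):
            chrom = rng.choice(["1", "2"])
            pos = rng.randrange(0, 7000)
            assert classify_end((chrom, pos), idx) == _oracle_classify(genes, chrom, pos)


def test_categorize_exonic_intronic_intergenic():
    idx = build_exon_index(THREE_GENES)
    exonic = CircRNA("1", 100, 500, "+", {})  # both ends in A's exons
    ann = categorize_circrna(exonic, idx)
    assert ann.category == "exonic" and ann.genes == ("A",)
    intronic = CircRNA("1", 250, 350, "+", {})  # both ends in A's first intron
    assert categorize_circrna(intronic, idx).category == "intronic"
    intergenic = CircRNA("1", 1200, 1600, "+", {})
    ann = categorize_circrna(intergenic, idx)
    assert ann.category == "intergenic" and ann.genes == ()


def test_categorize_mixed_ends_composite_label():
    idx = build_exon_index(THREE_GENES)
    mixed = CircRNA("1", 150, 350, "+", {})  # exonic start, intronic end
    assert categorize_circrna(mixed, idx).category == "exonic|intronic"
    assert (
        categorize_circrna(mixed, idx, intronic_any_end=True).category == "intronic"
    )
    half_out = CircRNA("1", 150, 1500, "+", {})  # exonic start, intergenic end
    assert categorize_circrna(half_out, idx).category == "exonic|intergenic"


def test_spanning_gene_qualifier():
    """A junction with exonic ends whose arc fully contains small nested genes."""
    genes = [
        _gene("HOST", "1", "-", [(100, 200), (9000, 9100)]),
        _gene("NEST1", "1", "+", [(3000, 3200)]),
        _gene("NEST2", "1", "+", [(5000, 5100)]),
    ]
    idx = build_exon_index(genes)
    c = CircRNA("1", 100, 9100, "-", {})
    ann = categorize_circrna(c, idx)
    assert ann.category == "exonic|intergenic spanning gene"
    assert ann.genes == ("HOST", "NEST1", "NEST2")
    assert ann.spanned_genes == ("NEST1", "NEST2")


def test_categorize_agrees_with_oracle_on_random_junctions():
    rng = random.Random(21)
    genes = []
    cursor = 0
    for i in range(30):
        cursor += rng.randint(500, 3000)
        exons = []
        pos = cursor
        for _ in range(rng.randint(1, 4)):
            exons.append((pos, pos + rng.randint(50, 200)))
            pos = exons[-1][1] + rng.randint(100, 400)
        genes.append(_gene(f"g{i}", "1", rng.choice("+-"), exons))
        cursor = pos
    idx = build_exon_index(genes)
    for _ in range(300):
        start = rng.randrange(0, cursor)
        c = CircRNA("1", start, start + rng.randint(1, 8000), "+", {})
        ann = categorize_circrna(c, idx)
        cat, gene_set = _oracle_categorize(genes, c)
        assert (ann.category, set(ann.genes)) == (cat, gene_set)


def test_circrnas_per_gene_counts_and_distribution():
    idx = build_exon_index(THREE_GENES)
    anns = [
        categorize_circrna(CircRNA("1", 100, 500, "+", {}), idx),
        categorize_circrna(CircRNA("1", 400, 900, "+", {}), idx),
        categorize_circrna(CircRNA("2", 50, 150, "+", {}), idx),
    ]
    per_gene, dist = circrnas_per_gene(anns)
    assert per_gene == {"A": 2, "C": 1}
    assert dist == {2: 1, 1: 1}


def test_multi_gene_circrna_increments_every_gene():
    genes = [
        _gene("F", "1", "+", [(100, 300)]),
        _gene("R", "1", "-", [(150, 350)]),
    ]
    idx = build_exon_index(genes)
    ann = categorize_circrna(CircRNA("1", 160, 290, "+", {}), idx)
    per_gene, _ = circrnas_per_gene([ann])
    assert per_gene == {"F": 1, "R": 1}
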