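"""Aggregate run statistics and their TSV/HTML rendering.

Every number in the report is derived on demand from the underlying tables
— percentages are never stored apart from their numerator and denominator,
so the rendered output can always be re-derived and cross-checked.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .annotate import CircAnnotation, circrnas_per_gene
from .consensus import MethodAgreement, method_agreement, per_sample_counts
from .express import CorrelationRecord
from .harmonize import CircRNA


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with round-half-up at ``decimals`` places.

    Built on decimal arithmetic so that e.g. 2.5% at 0 decimals rounds to 3,
    matching how report percentages are conventionally printed.
    """
    if denominator == 0:
        raise ZeroDivisionError("pct denominator is zero")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class CorrelationSummary:
    n: int = 0
    n_omitted: int = 0
    mean: float = float("nan")
    median: float = float("nan")
    n_above: int = 0  # rho > cutoff
    n_below: int = 0  # rho < -cutoff
    n_weak: int = 0  # |rho| <= cutoff
    cutoff: float = 0.5


@dataclass
class SummaryStats:
    """All aggregate counts behind the report; percentages are always re-derived."""

    n_samples: int = 0
    sample_ids: tuple[str, ...] = ()
    methods_enabled: tuple[str, ...] = ()
    n_union: int = 0
    per_method_counts: dict[str, int] = field(default_factory=dict)
    agreement_histogram: dict[int, int] = field(default_factory=dict)
    n_reliable: int = 0
    n_multi_method: int = 0  # detected by >= 2 methods
    category_counts: dict[str, int] = field(default_factory=dict)
    n_genes_with_circ: int = 0
    circ_per_gene_distribution: dict[int, int] = field(default_factory=dict)
    per_sample: dict[str, tuple[int, int]] = field(default_factory=dict)
    correlation: CorrelationSummary = field(default_factory=CorrelationSummary)


def summarize_correlations(
    records: list[CorrelationRecord], n_omitted: int = 0, cutoff: float = 0.5
) -> CorrelationSummary:
    if not records:
        return CorrelationSummary(n=0, n_omitted=n_omitted, cutoff=cutoff)
    rhos = np.array([r.rho for r in records])
    return CorrelationSummary(
        n=len(records),
        n_omitted=n_omitted,
        mean=float(rhos.mean()),
        median=float(np.median(rhos)),
        n_above=int((rhos > cutoff).sum()),
        n_below=int((rhos < -cutoff).sum()),
        n_weak=int((np.abs(rhos) <= cutoff).sum()),
        cutoff=cutoff,
    )


def build_summary(
    circrnas: list[CircRNA],
    reliable: list[CircRNA],
    annotations: list[CircAnnotation],
    correlations: tuple[list[CorrelationRecord], int] | None = None,
    methods_enabled: frozenset[str] | None = None,
) -> SummaryStats:
    """Recompute every aggregate statistic from the stage outputs."""
    from .io_formats import METHODS

    enabled = frozenset(methods_enabled) if methods_enabled else frozenset(METHODS)
    agreement: MethodAgreement = method_agreement(circrnas, enabled)
    samples = sorted({s for c in circrnas for s in c.samples()})
    cats: dict[str, int] = {}
    for a in annotations:
        cats[a.category] = cats.get(a.category, 0) + 1
    per_gene, dist = circrnas_per_gene(annotations)
    corr = (
        summarize_correlations(*correlations)
        if correlations is not None
        else CorrelationSummary()
    )
    return SummaryStats(
        n_samples=len(samples),
        sample_ids=tuple(samples),
        methods_enabled=tuple(sorted(enabled)),
        n_union=agreement.n_union,
        per_method_counts=agreement.per_method_counts,
        agreement_histogram=agreement.histogram,
        n_reliable=len(reliable),
        n_multi_method=sum(v for k, v in agreement.histogram.items() if k >= 2),
        category_counts=cats,
        n_genes_with_circ=len(per_gene),
        circ_per_gene_distribution=dist,
        per_sample=per_sample_counts(circrnas, reliable),
        correlation=corr,
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("".join(l + "\n" for l in lines))


def _versions() -> list[tuple[str, str]]:
    from importlib import metadata

    out = []
    for pkg in ("circconsensus", "numpy", "pandas", "scipy", "intervaltree", "gffutils", "click"):
        try:
            out.append((pkg, metadata.version(pkg)))
        except metadata.PackageNotFoundError:
            out.append((pkg, "unknown"))
    return out


def _html_table(header: list[str], rows: list[list]) -> str:
    parts = ["<table>", "<tr>" + "".join(f"<th>{html.escape(str(h))}</th>" for h in header) + "</tr>"]
    for row in rows:
        parts.append("<tr>" + "".join(f"<td>{html.escape(str(x))}</td>" for x in row) + "</tr>")
    parts.append("</table>")
    return "\n".join(parts)


def render(
    stats: SummaryStats,
    out_dir: str | Path,
    no_html: bool = False,
    versions: list[tuple[str, str]] | None = None,
) -> None:
    """Write ``stats/*.tsv`` and (unless ``no_html``) ``summary.html``.

    The HTML sections are, in order: run summary, detection and method
    agreement, reliable-set analyses, software versions. Rendering is
    deterministic given the stats and version strings.
    """
    out_dir = Path(out_dir)
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    if versions is None:
        versions = _versions()

    run_rows = [
        ["n_samples", stats.n_samples],
        ["sample_ids", ",".join(stats.sample_ids)],
        ["methods_enabled", ",".join(stats.methods_enabled)],
        ["n_union", stats.n_union],
        ["n_reliable", stats.n_reliable],
        ["n_genes_with_circrna", stats.n_genes_with_circ],
    ]
    _tsv(stats_dir / "run_summary.tsv", ["key", "value"], run_rows)

    method_rows = [
        [m, n, (pct(n, stats.n_union, 0) if stats.n_union else 0)]
        for m, n in sorted(stats.per_method_counts.items())
    ]
    _tsv(stats_dir / "per_method.tsv", ["method", "n_circrnas", "pct_of_union"], method_rows)

    hist_rows = [[k, v] for k, v in sorted(stats.agreement_histogram.items())]
    _tsv(stats_dir / "agreement_histogram.tsv", ["n_methods", "n_circrnas"], hist_rows)

    cat_rows = [
        [c, n, (pct(n, stats.n_reliable, 1) if stats.n_reliable else 0)]
        for c, n in sorted(stats.category_counts.items())
    ]
    _tsv(stats_dir / "categories.tsv", ["category", "n_circrnas", "pct_of_reliable"], cat_rows)

    sample_rows = [[s, u, r] for s, (u, r) in sorted(stats.per_sample.items())]
    _tsv(stats_dir / "per_sample.tsv", ["sample_id", "n_union", "n_reliable"], sample_rows)

    dist_rows = [[k, v] for k, v in sorted(stats.circ_per_gene_distribution.items())]
    _tsv(stats_dir / "circrnas_per_gene.tsv", ["n_circrnas", "n_genes"], dist_rows)

    c = stats.correlation
    corr_rows = [
        ["n_computable", c.n],
        ["n_omitted", c.n_omitted],
        ["mean_rho", c.mean],
        ["median_rho", c.median],
        [f"n_rho_above_{c.cutoff}", c.n_above],
        [f"n_rho_below_-{c.cutoff}", c.n_below],
        ["n_weak", c.n_weak],
    ]
    _tsv(stats_dir / "correlation_summary.tsv", ["key", "value"], corr_rows)

    _tsv(stats_dir / "versions.tsv", ["package", "version"], [list(v) for v in versions])

    if no_html:
        return

    sections = [
        "<h1>circRNA consensus analysis summary</h1>",
        "<h2>1. Run summary</h2>",
        _html_table(["key", "value"], run_rows),
        "<h2>2. Detection and method agreement</h2>",
        _html_table(["method", "n_circrnas", "pct_of_union"], method_rows),
        _html_table(["n_methods", "n_circrnas"], hist_rows),
        f"<p>{stats.n_reliable} reliable circRNAs selected from a union of "
        f"{stats.n_union} detected junctions.</p>",
        "<h2>3. Reliable-set analyses</h2>",
        _html_table(["category", "n_circrnas", "pct_of_reliable"], cat_rows),
        _html_table(["sample_id", "n_union", "n_reliable"], sample_rows),
        _html_table(["n_circrnas", "n_genes"], dist_rows),
        _html_table(["key", "value"], corr_rows),
        "<h2>4. Software versions</h2>",
        _html_table(["package", "version"], [list(v) for v in versions]),
    ]
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>circRNA consensus summary</title></head><body>\n"
        + "\n".join(sections)
        + "\n</body></html>\n"
    )
    (out_dir / "summary.html").write_text(doc)
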