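"""Synthetic detector-run generator with a planted ground truth.

Builds a toy genome annotation (non-overlapping multi-exon genes with
intergenic gaps), plants circRNAs of known category (exonic / intronic /
intergenic) with per-sample back-splice read counts, then emits what a real
run would leave on disk: one native-dialect file per (sample, method), the
GTF, per-sample gene expression tables, a sample metadata table, and a
machine-readable ``truth.tsv``.

The default rates emulate the detector heterogeneity seen in practice:
CIRI and find_circ have similar intermediate sensitivity, CIRCexplorer is
the most conservative, and testrealign both detects the most true junctions
and over-calls heavily — its private false-positive rate dwarfs the others,
so most of the detected union is single-method noise that the two-method
consensus removes. False positives are method-private by default (two
methods do not hallucinate the same junction); ``shared_fp`` plants
correlated errors to stress-test the consensus.

Every draw comes from one seeded generator, so a fixed seed yields
byte-identical output trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    DEFAULT_DIALECTS,
    METHODS,
    BackspliceCall,
    ConfigurationError,
    GeneModel,
    write_detector_file,
)

CATEGORIES = ("exonic", "intronic", "intergenic")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    sensitivity : per-method probability that a planted circRNA is detected
        (once per circRNA — a detector either finds a junction in the data
        or misses it everywhere).
    false_positive_rate : expected method-private spurious junctions per
        planted one.
    read_count_mean / read_count_dispersion : negative-binomial law for true
        per-sample back-splice read counts (zero-inflated in practice: small
        mean, small dispersion); each planted circRNA is guaranteed one
        sample with >= 2 reads so that the truth is recoverable under the
        default read threshold.
    category_mix : planted category proportions; heavily exonic, as reliable
        circRNA sets observed in practice are.
    """

    seed: int = 0
    n_genes: int = 60
    n_circrnas: int = 100
    n_samples: int = 4
    sensitivity: dict[str, float] = field(
        default_factory=lambda: {
            "circexplorer": 0.60,
            "ciri": 0.85,
            "findcirc": 0.85,
            "testrealign": 0.90,
        }
    )
    false_positive_rate: dict[str, float] = field(
        default_factory=lambda: {
            "circexplorer": 0.10,
            "ciri": 0.20,
            "findcirc": 0.25,
            "testrealign": 5.0,
        }
    )
    read_count_mean: float = 8.0
    read_count_dispersion: float = 2.0
    category_mix: dict[str, float] = field(
        default_factory=lambda: {"exonic": 0.90, "intronic": 0.05, "intergenic": 0.05}
    )
    total_mapped_reads: int = 1_000_000
    shared_fp: bool = False

    def validate(self) -> None:
        for m in METHODS:
            p = self.sensitivity.get(m)
            if p is None or not (0 <= p <= 1):
                raise ConfigurationError(f"sensitivity[{m!r}] must be in [0, 1]")
            if self.false_positive_rate.get(m, -1) < 0:
                raise ConfigurationError(f"false_positive_rate[{m!r}] must be >= 0")
        if set(self.category_mix) - set(CATEGORIES):
            raise ConfigurationError(f"unknown categories in mix: {self.category_mix}")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category_mix proportions must sum to 1")
        if self.n_samples < 1 or self.n_circrnas < 1 or self.n_genes < 3:
            raise ConfigurationError("need n_samples >= 1, n_circrnas >= 1, n_genes >= 3")
        if self.total_mapped_reads <= 0:
            raise ConfigurationError("total_mapped_reads must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [f"sample{i + 1}" for i in range(self.n_samples)]


@dataclass
class FixtureResult:
    """Paths and truth table of a generated dataset."""

    out_dir: Path
    spec: FixtureSpec
    truth: pd.DataFrame
    gtf_path: Path
    metadata_path: Path
    detector_paths: dict[tuple[str, str], Path]  # (sample, method) -> file
    expression_paths: dict[str, Path]


# --------------------------------------------------------------------------
# genome / annotation construction
# --------------------------------------------------------------------------

def _build_genes(spec: FixtureSpec, rng: np.random.Generator):
    """Non-overlapping genes over a few chromosomes, plus the intergenic gaps."""
    n_chroms = min(4, spec.n_genes)
    genes: list[GeneModel] = []
    gaps: list[tuple[str, int, int]] = []
    per_chrom = [spec.n_genes // n_chroms] * n_chroms
    for i in range(spec.n_genes % n_chroms):
        per_chrom[i] += 1
    gid = 0
    for ci in range(n_chroms):
        chrom = str(ci + 1)
        cursor = 10_000
        for _ in range(per_chrom[ci]):
            gid += 1
            n_exons = int(rng.integers(2, 6))
            exons = []
            pos = cursor
            for ei in range(n_exons):
                length = int(rng.integers(100, 301))
                exons.append((pos, pos + length))
                pos += length
                if ei < n_exons - 1:
                    pos += int(rng.integers(200, 801))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:04d}",
                    gene_name=f"gene{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            gap = int(rng.integers(5_000, 15_001))
            gaps.append((chrom, pos + 200, pos + gap - 200))
            cursor = pos + gap
    return genes, gaps


def _write_gtf(genes: list[GeneModel], path: Path) -> None:
    lines = []
    for g in genes:
        s0, e0 = g.span
        attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
        lines.append(
            f"{g.chrom}\tfixture\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t{attrs}"
        )
        tattrs = f'{attrs} transcript_id "{g.gene_id}.t1";'
        lines.append(
            f"{g.chrom}\tfixture\ttranscript\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t{tattrs}"
        )
        for s, e in g.exons:
            lines.append(
                f"{g.chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}"
            )
    path.write_text("".join(l + "\n" for l in lines))


# --------------------------------------------------------------------------
# planting
# --------------------------------------------------------------------------

@dataclass
class _Planted:
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    gene_id: str  # "" for intergenic
    counts: np.ndarray  # per-sample true read counts
    methods: tuple[str, ...]  # methods that detected it


def _plant_junction(category, genes, gaps, rng, used: set):
    for _ in range(200):
        if category == "exonic":
            g = genes[int(rng.integers(len(genes)))]
            i = int(rng.integers(len(g.exons)))
            j = int(rng.integers(i, len(g.exons)))
            key = (g.chrom, g.exons[i][0], g.exons[j][1])
            if key in used:
                continue
            return key, g.strand, g.gene_id
        if category == "intronic":
            g = genes[int(rng.integers(len(genes)))]
            if len(g.exons) < 2:
                continue
            k = int(rng.integers(len(g.exons) - 1))
            lo, hi = g.exons[k][1], g.exons[k + 1][0]
            if hi - lo < 120:
                continue
            start = int(rng.integers(lo + 5, hi - 110))
            end = int(rng.integers(start + 50, hi - 5))
            key = (g.chrom, start, end)
            if key in used:
                continue
            return key, g.strand, g.gene_id
        # intergenic
        chrom, lo, hi = gaps[int(rng.integers(len(gaps)))]
        if hi - lo < 400:
            continue
        start = int(rng.integers(lo, hi - 300))
        end = int(rng.integers(start + 100, hi))
        key = (chrom, start, end)
        if key in used:
            continue
        return key, ("+" if rng.random() < 0.5 else "-"), ""
    raise RuntimeError(f"could not place a unique {category} junction; enlarge the genome")


def _true_counts(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    r = spec.read_count_dispersion
    p = r / (r + spec.read_count_mean)
    counts = rng.negative_binomial(r, p, size=spec.n_samples)
    if counts.max() < 2:
        counts[int(rng.integers(spec.n_samples))] = 2
    return counts


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate(spec: FixtureSpec, out_dir: str | Path) -> FixtureResult:
    """Generate the full synthetic dataset under ``out_dir``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes, gaps = _build_genes(spec, rng)
    gtf_path = out_dir / "annotation.gtf"
    _write_gtf(genes, gtf_path)

    # planted truth
    n_per_cat = rng.multinomial(
        spec.n_circrnas, [spec.category_mix.get(c, 0.0) for c in CATEGORIES]
    )
    used: set = set()
    planted: list[_Planted] = []
    for cat, n in zip(CATEGORIES, n_per_cat):
        for _ in range(int(n)):
            key, strand, gene_id = _plant_junction(cat, genes, gaps, rng, used)
            used.add(key)
            counts = _true_counts(spec, rng)
            detected = tuple(
                m for m in METHODS if rng.random() < spec.sensitivity[m]
            )
            planted.append(
                _Planted(key[0], key[1], key[2], strand, cat, gene_id, counts, detected)
            )
    planted.sort(key=lambda p: (p.chrom, p.start, p.end))

    # method-private false positives
    fp_calls: dict[str, list] = {m: [] for m in METHODS}
    for m in METHODS:
        n_fp = int(rng.poisson(spec.false_positive_rate[m] * spec.n_circrnas))
        for _ in range(n_fp):
            key, strand, _ = _plant_junction("intergenic", genes, gaps, rng, used)
            used.add(key)
            sample = spec.sample_ids[int(rng.integers(spec.n_samples))]
            fp_calls[m].append((key, strand, sample, int(rng.integers(1, 6))))
    if spec.shared_fp:
        n_shared = int(rng.poisson(0.05 * spec.n_circrnas))
        for _ in range(n_shared):
            key, strand, _ = _plant_junction("intergenic", genes, gaps, rng, used)
            used.add(key)
            pair = rng.choice(len(METHODS), size=2, replace=False)
            sample = spec.sample_ids[int(rng.integers(spec.n_samples))]
            count = int(rng.integers(2, 6))
            for mi in pair:
                fp_calls[METHODS[mi]].append((key, strand, sample, count))

    # emit detector files per (sample, method), native conventions
    samples_dir = out_dir / "detectors"
    samples_dir.mkdir(exist_ok=True)
    detector_paths: dict[tuple[str, str], Path] = {}
    for si, sample in enumerate(spec.sample_ids):
        for m in METHODS:
            calls = []
            for p in planted:
                if m not in p.methods or p.counts[si] == 0:
                    continue
                calls.append((p.chrom, p.start, p.end, p.strand, int(p.counts[si])))
            for key, strand, fp_sample, count in fp_calls[m]:
                if fp_sample == sample:
                    calls.append((key[0], key[1], key[2], strand, count))
            calls.sort()
            dialect = DEFAULT_DIALECTS[m]
            native = [
                BackspliceCall(
                    method=m,
                    sample_id=sample,
                    chrom=chrom,
                    start_native=start - dialect.start_offset,
                    end_native=end - dialect.end_offset,
                    strand=strand,
                    read_count=count,
                )
                for chrom, start, end, strand, count in calls
            ]
            ext = "ciri.tsv" if m == "ciri" else f"{m}.bed"
            path = samples_dir / f"{sample}.{ext}"
            write_detector_file(native, m, path)
            detector_paths[(sample, m)] = path

    # per-sample gene expression tables (FPKM + raw count), ~10% silent genes
    expr_dir = out_dir / "expression"
    expr_dir.mkdir(exist_ok=True)
    expression_paths: dict[str, Path] = {}
    base_level = rng.lognormal(mean=3.0, sigma=1.0, size=len(genes))
    silent = rng.random(len(genes)) < 0.1
    for sample in spec.sample_ids:
        noise = rng.lognormal(mean=0.0, sigma=0.4, size=len(genes))
        fpkm = np.where(silent, 0.0, base_level * noise)
        raw = np.floor(fpkm * 20).astype(int)
        lines = ["gene_id\tFPKM\traw_count"]
        for g, f, r in zip(genes, fpkm, raw):
            lines.append(f"{g.gene_id}\t{f:.4f}\t{int(r)}")
        path = expr_dir / f"{sample}.tsv"
        path.write_text("".join(l + "\n" for l in lines))
        expression_paths[sample] = path

    # truth table
    rows = []
    for p in planted:
        row = {
            "circ_id": f"{p.chrom}:{p.start + 1}-{p.end}:{p.strand}",
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "strand": p.strand,
            "category": p.category,
            "gene_id": p.gene_id,
            "methods": ",".join(p.methods),
        }
        for si, sample in enumerate(spec.sample_ids):
            row[f"count_{sample}"] = int(p.counts[si])
        rows.append(row)
    truth = pd.DataFrame(rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    # sample metadata for the CLI; paths relative to the metadata file keep
    # the fixture tree relocatable
    meta_rows = ["sample_id\tmethod\tpath\ttotal_mapped_reads\texpression_path"]
    for sample in spec.sample_ids:
        for m in METHODS:
            meta_rows.append(
                f"{sample}\t{m}\t{detector_paths[(sample, m)].relative_to(out_dir)}\t"
                f"{spec.total_mapped_reads}\t{expression_paths[sample].relative_to(out_dir)}"
            )
    metadata_path = out_dir / "metadata.tsv"
    metadata_path.write_text("".join(l + "\n" for l in meta_rows))

    return FixtureResult(
        out_dir=out_dir,
        spec=spec,
        truth=truth,
        gtf_path=gtf_path,
        metadata_path=metadata_path,
        detector_paths=detector_paths,
        expression_paths=expression_paths,
    )


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def score_against_truth(reliable, truth: pd.DataFrame) -> tuple[float, int]:
    """(sensitivity, false_discovery_count) of a reliable set against the planted truth.

    ``reliable`` is a list of harmonized circRNAs (or (chrom, start, end)
    keys). Sensitivity is the fraction of planted junctions recovered; the
    false-discovery count is the number of reliable junctions absent from
    the truth.
    """
    truth_keys = {
        (str(r.chrom), int(r.start), int(r.end)) for r in truth.itertuples()
    }
    got = set()
    for c in reliable:
        got.add(c if isinstance(c, tuple) else c.key)
    recovered = len(truth_keys & got)
    sensitivity = recovered / len(truth_keys) if truth_keys else float("nan")
    return sensitivity, len(got - truth_keys)


def detection_probability(sensitivities: list[float], min_methods: int = 2) -> float:
    """Closed-form P(at least ``min_methods`` of the independent detectors fire).

    Exact Poisson-binomial tail over all method subsets; used as the oracle
    for the stochastic-dropout recovery rate.
    """
    n = len(sensitivities)
    total = 0.0
    for k in range(min_methods, n + 1):
        for subset in itertools.combinations(range(n), k):
            prob = 1.0
            for i in range(n):
                prob *= sensitivities[i] if i in subset else 1 - sensitivities[i]
            total += prob
    return total
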