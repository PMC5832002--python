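"""circRNA expression: RPM normalization, matrices, fold changes, correlations.

circRNA abundance is the number of back-splice-spanning reads, normalized to
reads per million total mapped reads (RPM); gene abundance arrives as FPKM
from the linear-transcript quantification. When several methods quantify the
same junction in the same sample, the per-sample count defaults to the
maximum over methods — the methods observe the same molecules, so summing
would double-count.

Fold changes are computed without replicates, so a pseudocount (default
1 RPM) guards the log against the zeros that are common in back-splice
counts. circRNA-to-host-gene association is descriptive: pairwise Spearman
correlations across samples, with no significance testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import CircAnnotation
from .harmonize import CircRNA, circrna_id
from .io_formats import ConfigurationError, SampleExpression

COUNT_RULES = ("max", "sum", "mean")


@dataclass
class ExpressionMatrix:
    """Rows (circRNA or gene ids) x samples, tagged with its unit."""

    values: pd.DataFrame
    unit: str  # "RPM", "FPKM" or "raw"

    def __post_init__(self):
        if self.unit not in ("RPM", "FPKM", "raw"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("row and column ids must be unique")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit: {self.unit}\n")
            self.values.to_csv(fh, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            first = fh.readline().strip()
            unit = first.removeprefix("# unit: ")
            df = pd.read_csv(fh, sep="\t", index_col="id")
        df.index.name = None
        return cls(values=df, unit=unit)


def rpm(read_count: int, total_mapped_reads: int) -> float:
    """Reads per million mapped: ``count * 1e6 / total``."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return read_count * 1e6 / total_mapped_reads


def _reduce_counts(counts: list[int], rule: str) -> float:
    if rule == "max":
        return max(counts)
    if rule == "sum":
        return sum(counts)
    return sum(counts) / len(counts)


def circrna_matrix(
    reliable: list[CircRNA],
    totals: dict[str, int],
    count_rule: str = "max",
    unit: str = "RPM",
) -> ExpressionMatrix:
    """Build the circRNA x sample expression matrix.

    Per cell, the (sample, method) read counts are reduced by ``count_rule``
    and, unless ``unit="raw"``, normalized to RPM with that sample's total
    mapped reads. Absent evidence is 0.
    """
    if count_rule not in COUNT_RULES:
        raise ConfigurationError(f"unknown count rule {count_rule!r}")
    samples = sorted(totals)
    needed = {s for c in reliable for s in c.samples()}
    missing = needed - set(samples)
    if missing:
        raise ConfigurationError(f"no total_mapped_reads for samples: {sorted(missing)}")
    rows = {}
    for c in reliable:
        per_sample = {}
        for (s, _m), n in c.evidence.items():
            per_sample.setdefault(s, []).append(n)
        row = []
        for s in samples:
            if s not in per_sample:
                row.append(0.0)
                continue
            count = _reduce_counts(per_sample[s], count_rule)
            row.append(count if unit == "raw" else rpm(count, totals[s]))
        rows[circrna_id(c)] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    if df.empty:
        df = pd.DataFrame(np.empty((0, len(samples))), columns=samples)
    return ExpressionMatrix(values=df, unit=unit)


def gene_matrix(expressions: list[SampleExpression]) -> ExpressionMatrix:
    """Gene x sample FPKM matrix from per-sample expression tables; absent genes are 0."""
    cols = {}
    for ex in expressions:
        if ex.sample_id in cols:
            raise ConfigurationError(f"duplicate sample id {ex.sample_id!r}")
        cols[ex.sample_id] = {g: fpkm for g, (fpkm, _) in ex.genes.items()}
    df = pd.DataFrame(cols).fillna(0.0).sort_index()
    df = df[sorted(df.columns)]
    return ExpressionMatrix(values=df, unit="FPKM")


def log2fc(a: float, b: float, pseudocount: float = 1.0) -> float:
    """log2((a + p) / (b + p)); antisymmetric in (a, b)."""
    if a < 0 or b < 0:
        raise ValueError("expression values must be non-negative")
    if pseudocount <= 0 and (a == 0 or b == 0):
        raise ValueError("pseudocount must be positive when values can be zero")
    return math.log2((a + pseudocount) / (b + pseudocount))


def fc_threshold_counts(fc: list[float], threshold: float = 1.5) -> tuple[int, int]:
    """(n_up, n_down): values strictly above +threshold / below -threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(fc, dtype=float)
    return int((arr > threshold).sum()), int((arr < -threshold).sum())


def cumulative_share(matrix: ExpressionMatrix, sample: str, fraction: float) -> int:
    """Minimal number of rows, in descending order, covering ``fraction`` of the column total."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    col = matrix.values[sample].to_numpy()
    total = col.sum()
    if total <= 0:
        raise ValueError(f"column {sample!r} has no expression")
    ordered = np.sort(col)[::-1]
    cum = np.cumsum(ordered)
    # float-safe: never demand more than the attainable total
    target = min(fraction * total, total)
    return int(np.searchsorted(cum, target - 1e-9 * total) + 1)


@dataclass(frozen=True)
class CorrelationRecord:
    """Spearman correlation between one circRNA and one overlapping gene."""

    circrna_id: str
    gene_id: str
    rho: float
    n_samples: int


def correlate(
    circ_m: ExpressionMatrix,
    gene_m: ExpressionMatrix,
    annotations: list[CircAnnotation],
    min_samples: int = 3,
) -> tuple[list[CorrelationRecord], int]:
    """Spearman rho (average ranks for ties) for each computable circRNA/gene pair.

    A pair is computable when the circRNA and gene share at least
    ``min_samples`` samples and neither expression vector is constant;
    other pairs are omitted and counted. Returns (records, n_omitted).
    """
    shared = [s for s in circ_m.values.columns if s in set(gene_m.values.columns)]
    records: list[CorrelationRecord] = []
    n_omitted = 0
    gene_index = set(gene_m.values.index)
    circ_index = set(circ_m.values.index)
    for a in annotations:
        if a.circrna_id not in circ_index:
            continue
        cv = circ_m.values.loc[a.circrna_id, shared].to_numpy(dtype=float)
        for g in a.genes:
            if g not in gene_index:
                n_omitted += 1
                continue
            gv = gene_m.values.loc[g, shared].to_numpy(dtype=float)
            if len(shared) < min_samples or np.ptp(cv) == 0 or np.ptp(gv) == 0:
                n_omitted += 1
                continue
            rho = stats.spearmanr(cv, gv).statistic
            records.append(
                CorrelationRecord(
                    circrna_id=a.circrna_id, gene_id=g, rho=float(rho), n_samples=len(shared)
                )
            )
    return records, n_omitted
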