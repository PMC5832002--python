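"""Reliable-circRNA selection and method-agreement statistics.

The reliable set is, by default, the junctions detected by at least two
independent methods and supported by at least two back-splice reads.
Requiring multiple independent detections trims method-private false calls
while the read threshold trims single-read noise; both thresholds are
user-tunable, and setting both to 1 recovers the full union (maximum
sensitivity).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .harmonize import CircRNA
from .io_formats import METHODS, ConfigurationError

SUPPORT_STATISTICS = ("max", "sum_over_methods", "sum_over_samples")


@dataclass(frozen=True)
class ConsensusConfig:
    """Selection thresholds for the reliable circRNA set.

    min_methods : minimum number of distinct enabled methods detecting the junction.
    min_reads : minimum read support under ``support_statistic``.
    methods_enabled : the detector subset considered; evidence from other
        methods is ignored entirely.
    scope : "pooled" counts methods across all samples together; "per_sample"
        requires the method quorum within at least one single sample.
    support_statistic : how per-(sample, method) read counts reduce to one
        support value. "max" (default) takes the single best entry, avoiding
        inflation from summing correlated estimates of the same molecules;
        "sum_over_methods" takes, per sample, the cross-method sum and then
        the best sample; "sum_over_samples" sums each method across samples
        and takes the best method.
    """

    min_methods: int = 2
    min_reads: int = 2
    methods_enabled: frozenset[str] = frozenset(METHODS)
    scope: str = "pooled"
    support_statistic: str = "max"

    def validate(self) -> None:
        if self.min_methods < 1 or self.min_reads < 1:
            raise ConfigurationError("min_methods and min_reads must be >= 1")
        unknown = set(self.methods_enabled) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
        if self.min_methods > len(self.methods_enabled):
            raise ConfigurationError(
                f"min_methods={self.min_methods} exceeds the "
                f"{len(self.methods_enabled)} enabled methods"
            )
        if self.scope not in ("pooled", "per_sample"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if self.support_statistic not in SUPPORT_STATISTICS:
            raise ConfigurationError(
                f"unknown support statistic {self.support_statistic!r}"
            )


@dataclass
class MethodAgreement:
    """Per-method detection counts and the n-methods agreement histogram."""

    per_method_counts: dict[str, int]
    histogram: dict[int, int]
    n_union: int


def _enabled_evidence(c: CircRNA, enabled: frozenset[str]):
    return {k: v for k, v in c.evidence.items() if k[1] in enabled}


def _support(evidence: dict, statistic: str) -> int:
    if not evidence:
        return 0
    if statistic == "max":
        return max(evidence.values())
    if statistic == "sum_over_methods":
        per_sample = Counter()
        for (s, _), n in evidence.items():
            per_sample[s] += n
        return max(per_sample.values())
    per_method = Counter()
    for (_, m), n in evidence.items():
        per_method[m] += n
    return max(per_method.values())


def select_reliable(circrnas: list[CircRNA], cfg: ConsensusConfig) -> list[CircRNA]:
    """Return the circRNAs passing both the method quorum and the read threshold.

    Both conditions are evaluated conjunctively on the same evidence
    (restricted to the enabled methods); input order is preserved.
    """
    cfg.validate()
    out = []
    for c in circrnas:
        ev = _enabled_evidence(c, cfg.methods_enabled)
        if not ev:
            continue
        if cfg.scope == "pooled":
            n_methods = len({m for (_, m) in ev})
        else:
            per_sample: dict[str, set] = {}
            for (s, m) in ev:
                per_sample.setdefault(s, set()).add(m)
            n_methods = max(len(ms) for ms in per_sample.values())
        if n_methods < cfg.min_methods:
            continue
        if _support(ev, cfg.support_statistic) < cfg.min_reads:
            continue
        out.append(c)
    return out


def method_agreement(
    circrnas: list[CircRNA], methods_enabled: frozenset[str] = frozenset(METHODS)
) -> MethodAgreement:
    """Count detections per method and build the n-methods histogram.

    A circRNA counts once per method regardless of how many samples the
    method saw it in; the histogram bins circRNAs by how many enabled
    methods detected them. Histogram counts sum to the union size.
    """
    per_method = {m: 0 for m in sorted(methods_enabled)}
    histogram: Counter = Counter()
    n_union = 0
    for c in circrnas:
        methods = {m for (_, m) in c.evidence if m in methods_enabled}
        if not methods:
            continue
        n_union += 1
        for m in methods:
            per_method[m] += 1
        histogram[len(methods)] += 1
    return MethodAgreement(per_method_counts=per_method, histogram=dict(histogram), n_union=n_union)


def per_sample_counts(
    circrnas: list[CircRNA], reliable: list[CircRNA]
) -> dict[str, tuple[int, int]]:
    """Per sample: number of circRNAs with any read evidence there, in the
    whole detected set and in the reliable subset."""
    reliable_keys = {c.key for c in reliable}
    union_n: Counter = Counter()
    reliable_n: Counter = Counter()
    for c in circrnas:
        for s in c.samples():
            union_n[s] += 1
            if c.key in reliable_keys:
                reliable_n[s] += 1
    return {s: (union_n[s], reliable_n[s]) for s in sorted(union_n)}
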