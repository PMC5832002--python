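"""RPM normalization, matrices, fold changes, cumulative shares, correlations."""

import math
import random

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circconsensus.annotate import CircAnnotation
from circconsensus.express import (
    ExpressionMatrix,
    circrna_matrix,
    correlate,
    cumulative_share,
    fc_threshold_counts,
    gene_matrix,
    log2fc,
    rpm,
)
from circconsensus.harmonize import CircRNA, circrna_id
from circconsensus.io_formats import ConfigurationError, SampleExpression


def test_rpm_basic_values():
    assert rpm(0, 10**6) == 0
    assert rpm(7, 10**6) == 7
    assert rpm(5, 2 * 10**6) == 2.5
    with pytest.raises(ValueError):
        rpm(5, 0)


@given(st.integers(0, 10**6), st.integers(1, 10**9))
def test_rpm_linear_and_scale_invariant(count, total):
    assert rpm(2 * count, total) == 2 * rpm(count, total)
    assert rpm(2 * count, 2 * total) == rpm(count, total)


def _circ(start, evidence):
    return CircRNA("1", start, start + 1000, "+", evidence)


def test_circrna_matrix_rules_and_zeros():
    c = _circ(0, {("s1", "ciri"): 3, ("s1", "findcirc"): 5, ("s2", "ciri"): 2})
    totals = {"s1": 10**6, "s2": 10**6, "s3": 10**6}
    m = circrna_matrix([c], totals, count_rule="max")
    row = m.values.loc[circrna_id(c)]
    assert (row["s1"], row["s2"], row["s3"]) == (5.0, 2.0, 0.0)
    m_sum = circrna_matrix([c], totals, count_rule="sum")
    assert m_sum.values.loc[circrna_id(c), "s1"] == 8.0
    m_mean = circrna_matrix([c], totals, count_rule="mean")
    assert m_mean.values.loc[circrna_id(c), "s1"] == 4.0


def test_circrna_matrix_requires_totals_for_all_samples():
    c = _circ(0, {("s1", "ciri"): 3})
    with pytest.raises(ConfigurationError, match="s1"):
        circrna_matrix([c], {"s2": 10**6})


def test_matrix_tsv_round_trip(tmp_path):
    c = _circ(0, {("s1", "ciri"): 3})
    m = circrna_matrix([c], {"s1": 10**6, "s2": 2 * 10**6})
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = ExpressionMatrix.from_tsv(path)
    assert back.unit == "RPM"
    pd.testing.assert_frame_equal(back.values, m.values)


def test_gene_matrix_from_sample_expressions():
    exprs = [
        SampleExpression("s1", {"G1": (10.0, 100), "G2": (0.0, 0)}, 1000),
        SampleExpression("s2", {"G1": (20.0, 200)}, 1000),
    ]
    m = gene_matrix(exprs)
    assert m.unit == "FPKM"
    assert m.values.loc["G2", "s2"] == 0.0  # absent gene filled with 0
    assert m.values.loc["G1", "s2"] == 20.0


def test_log2fc_values_and_errors():
    assert log2fc(4.0, 4.0, 1.0) == 0
    assert log2fc(4.0, 1.0, 0.0) == 2
    with pytest.raises(ValueError):
        log2fc(0.0, 0.0, 0.0)


@given(
    st.floats(0, 1e6, allow_nan=False),
    st.floats(0, 1e6, allow_nan=False),
    st.floats(0.01, 10),
)
def test_log2fc_antisymmetry(a, b, p):
    assert math.isclose(log2fc(a, b, p), -log2fc(b, a, p), abs_tol=1e-9)


def test_fc_threshold_counts():
    assert fc_threshold_counts([0.0, 0.0, 0.0]) == (0, 0)
    assert fc_threshold_counts([2, -2, 1], threshold=1.5) == (1, 1)
    vec = [1.6, 1.5, -1.5, -1.6, 0.2, 3.0]
    n_up, n_down = fc_threshold_counts(vec, 1.5)
    assert (n_up, n_down) == (
        sum(1 for v in vec if v > 1.5),
        sum(1 for v in vec if v < -1.5),
    )


def _matrix_from_column(values):
    df = pd.DataFrame({"s1": values}, index=[f"r{i}" for i in range(len(values))])
    return ExpressionMatrix(values=df, unit="RPM")


def _share_oracle(values, fraction):
    ordered = sorted(values, reverse=True)
    target = fraction * sum(values)
    acc = 0.0
    for i, v in enumerate(ordered, start=1):
        acc += v
        if acc >= target - 1e-9 * sum(values):
            return i
    return len(ordered)


def test_cumulative_share_trivial_cases():
    assert cumulative_share(_matrix_from_column([1.0] * 7), "s1", 1.0) == 7
    assert cumulative_share(_matrix_from_column([75.0, 25.0]), "s1", 0.75) == 1
    with pytest.raises(ValueError):
        cumulative_share(_matrix_from_column([0.0, 0.0]), "s1", 0.5)


def test_cumulative_share_matches_prefix_sum_oracle():
    rng = random.Random(13)
    for _ in range(50):
        values = [rng.randint(0, 50) for _ in range(rng.randint(1, 30))]
        if sum(values) == 0:
            values[0] = 1
        m = _matrix_from_column([float(v) for v in values])
        for fraction in (0.1, 0.5, 0.75, 0.9, 1.0):
            assert cumulative_share(m, "s1", fraction) == _share_oracle(values, fraction)


def test_cumulative_share_non_decreasing_in_fraction():
    m = _matrix_from_column([50.0, 30.0, 15.0, 5.0])
    shares = [cumulative_share(m, "s1", f) for f in (0.2, 0.5, 0.8, 0.95, 1.0)]
    assert shares == sorted(shares)


# -- Spearman ---------------------------------------------------------------

def _spearman_oracle(x, y):
    """Average ranks by hand, then plain Pearson on the ranks."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def _correlate_pair(cv, gv, min_samples=3):
    samples = [f"s{i}" for i in range(len(cv))]
    circ = ExpressionMatrix(
        pd.DataFrame([cv], index=["circ1"], columns=samples, dtype=float), "RPM"
    )
    gene = ExpressionMatrix(
        pd.DataFrame([gv], index=["G1"], columns=samples, dtype=float), "FPKM"
    )
    ann = [CircAnnotation("circ1", "exonic", ("G1",), ("G1",))]
    return correlate(circ, gene, ann, min_samples=min_samples)


def test_correlate_perfect_monotone():
    records, _ = _correlate_pair([1, 2, 3, 4], [10, 20, 30, 40])
    assert records[0].rho == pytest.approx(1.0)
    records, _ = _correlate_pair([1, 2, 3, 4], [40, 30, 20, 10])
    assert records[0].rho == pytest.approx(-1.0)


def test_correlate_tied_vectors_match_hand_ranks():
    records, _ = _correlate_pair([1, 1, 2, 3], [2, 5, 5, 9])
    assert records[0].rho == pytest.approx(_spearman_oracle([1, 1, 2, 3], [2, 5, 5, 9]))


@given(
    st.integers(3, 8).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 5), min_size=n, max_size=n),
            st.lists(st.integers(0, 5), min_size=n, max_size=n),
        )
    )
)
def test_correlate_matches_average_rank_oracle(pair):
    cv, gv = pair
    records, n_omitted = _correlate_pair(cv, gv)
    if len(set(cv)) == 1 or len(set(gv)) == 1:
        assert records == [] and n_omitted == 1  # constant vector: not computable
    else:
        assert records[0].rho == pytest.approx(_spearman_oracle(cv, gv))


def test_correlate_rho_invariant_under_monotone_transform():
    cv, gv = [1.0, 4.0, 2.0, 8.0, 5.0], [3.0, 9.0, 1.0, 20.0, 11.0]
    (r1,), _ = _correlate_pair(cv, gv)
    (r2,), _ = _correlate_pair([v**2 for v in cv], [math.log1p(v) for v in gv])
    assert r1.rho == pytest.approx(r2.rho)


def test_correlate_requires_min_samples():
    records, n_omitted = _correlate_pair([1, 2], [2, 1], min_samples=3)
    assert records == [] and n_omitted == 1


def test_correlate_skips_unknown_genes_and_counts_them():
    samples = ["s0", "s1", "s2", "s3"]
    circ = ExpressionMatrix(
        pd.DataFrame([[1, 2, 3, 4]], index=["circ1"], columns=samples, dtype=float),
        "RPM",
    )
    gene = ExpressionMatrix(
        pd.DataFrame([[1, 2, 3, 4]], index=["G1"], columns=samples, dtype=float),
        "FPKM",
    )
    ann = [CircAnnotation("circ1", "exonic", ("G1", "MISSING"), ("G1", "MISSING"))]
    records, n_omitted = correlate(circ, gene, ann)
    assert len(records) == 1 and n_omitted == 1
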