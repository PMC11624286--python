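"""Context classification, weighted methylation, rank-sum/BH and Wilson."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from ltrburst.methylation import (
    classify_context,
    compare_methylation,
    conversion_rate,
    read_cytosine_report,
    revcomp,
    weighted_methylation,
    weighted_pct,
    wilson_interval,
    write_cytosine_report,
)


def make_report(rows):
    """rows: (chrom, pos, strand, meth, unmeth, context)"""
    return pd.DataFrame(
        [(c, p, s, m, u, ctx, "NNN") for c, p, s, m, u, ctx in rows],
        columns=[
            "chrom",
            "pos",
            "strand",
            "count_methylated",
            "count_unmethylated",
            "context",
            "trinucleotide",
        ],
    )


@pytest.mark.parametrize(
    "seq,pos,strand,expected",
    [
        ("CGA", 0, "+", "CG"),
        ("CAG", 0, "+", "CHG"),
        ("CAT", 0, "+", "CHH"),
        ("TCG", 2, "-", "CG"),  # reverse complement reads CGA
        ("CTG", 2, "-", "CHG"),
        ("ATG", 2, "-", "CHH"),
        ("C", 0, "+", "CHH"),  # edge: missing neighbours count as H
    ],
)
def test_classify_context_examples(seq, pos, strand, expected):
    assert classify_context(seq, pos, strand) == expected


def test_classify_context_requires_cytosine():
    with pytest.raises(ValueError):
        classify_context("ACG", 0, "+")


@given(
    st.text(alphabet="ACGT", min_size=5, max_size=30),
    st.integers(min_value=0, max_value=29),
)
@settings(max_examples=200, derandomize=True)
def test_minus_strand_context_matches_revcomp_oracle(seq, pos):
    """The minus-strand context equals the plus-strand context of the
    reverse complement at the mirrored position."""
    if pos >= len(seq) or seq[pos] != "G":
        return
    rc = revcomp(seq)
    mirrored = len(seq) - 1 - pos
    assert classify_context(seq, pos, "-") == classify_context(rc, mirrored, "+")


def test_weighted_methylation_is_coverage_weighted():
    """(9,1) and (0,30) pool to 9/40 = 22.5%, not the per-site mean 45%."""
    rep = make_report(
        [("c", 10, "+", 9, 1, "CG"), ("c", 20, "+", 0, 30, "CG")]
    )
    s = weighted_methylation(rep)["CG"]
    assert s.pct == pytest.approx(22.5)
    assert s.meth == 9 and s.total == 40 and s.n_cytosines == 2


def test_weighted_methylation_symmetric_and_extremes():
    rep = make_report(
        [("c", 1, "+", 3, 1, "CHG"), ("c", 2, "+", 1, 3, "CHG")]
    )
    assert weighted_methylation(rep)["CHG"].pct == pytest.approx(50.0)
    full = make_report([("c", 1, "+", 7, 0, "CHH")])
    assert weighted_methylation(full)["CHH"].pct == pytest.approx(100.0)


def test_zero_coverage_is_undefined_not_zero():
    rep = make_report([("c", 1, "+", 0, 0, "CG")])
    s = weighted_methylation(rep)["CG"]
    assert not s.defined
    assert math.isnan(s.pct)


@given(
    st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=20
    ),
    st.integers(min_value=2, max_value=5),
)
@settings(max_examples=100, derandomize=True)
def test_weighted_methylation_partition_invariance(counts, k):
    """Splitting records into batches and summing counts never changes the
    pooled percentage (count additivity)."""
    rows = [("c", i, "+", m, u, "CG") for i, (m, u) in enumerate(counts)]
    whole = weighted_methylation(make_report(rows))["CG"]
    parts = [rows[i::k] for i in range(k)]
    meth = sum(weighted_methylation(make_report(p))["CG"].meth for p in parts if p)
    total = sum(weighted_methylation(make_report(p))["CG"].total for p in parts if p)
    assert meth == whole.meth and total == whole.total


def test_conversion_rate_arithmetic():
    # 1 methylated of 1000 observations
    rep = make_report(
        [("pt", 0, "+", 1, 0, "CHH")]
        + [("pt", i, "+", 0, 1, "CHH") for i in range(1, 1000)]
    )
    assert conversion_rate(rep, "pt") == pytest.approx(99.9)
    all_conv = make_report([("pt", i, "+", 0, 2, "CG") for i in range(5)])
    assert conversion_rate(all_conv, "pt") == pytest.approx(100.0)
    with pytest.raises(ValueError):
        conversion_rate(rep, "missing")


def _bh_oracle(pvals):
    """Independent step-up implementation."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[idx] * m / rank)
        adj[idx] = prev
    return adj


def test_compare_methylation_bh_matches_step_up_oracle():
    rng = np.random.default_rng(3)
    ga = {c: rng.uniform(0, 1, 30) for c in ("CG", "CHG", "CHH")}
    gb = {c: rng.uniform(0, 1, 30) + (0.3 if c == "CHH" else 0.0) for c in ga}
    df = compare_methylation(ga, gb)
    expected = _bh_oracle(df["p_raw"].to_numpy())
    assert np.allclose(df["p_adj"].to_numpy(), expected)


def test_compare_methylation_identical_groups_not_significant():
    vals = {c: np.linspace(0, 1, 20) for c in ("CG", "CHG", "CHH")}
    df = compare_methylation(vals, vals)
    assert (df["p_adj"] >= 0.05).all()
    assert not df["significant"].any()


def test_compare_methylation_single_comparison_adjusted_equals_raw():
    rng = np.random.default_rng(1)
    ga = {"CG": rng.uniform(0, 1, 10)}
    gb = {"CG": rng.uniform(0, 1, 10)}
    df = compare_methylation(ga, gb, contexts=("CG",))
    assert df["p_adj"].iloc[0] == pytest.approx(df["p_raw"].iloc[0])


def test_compare_methylation_small_group_is_na():
    df = compare_methylation({"CG": [0.5]}, {"CG": [0.1, 0.2, 0.3]}, contexts=("CG",))
    assert math.isnan(df["p_raw"].iloc[0])


def test_wilson_interval_frozen_values():
    lo, hi = wilson_interval(0, 10)
    assert lo == pytest.approx(0.0, abs=1e-12)
    assert hi == pytest.approx(0.27753, abs=1e-4)
    lo2, hi2 = wilson_interval(10, 10)
    assert (lo2, hi2) == pytest.approx((1 - hi, 1.0), abs=1e-12)
    lo3, hi3 = wilson_interval(5, 10)
    assert lo3 + hi3 == pytest.approx(1.0)


@given(st.integers(0, 200), st.integers(1, 200))
@settings(max_examples=200, derandomize=True)
def test_wilson_mirror_symmetry_and_library_agreement(k, n):
    if k > n:
        return
    lo, hi = wilson_interval(k, n)
    mlo, mhi = wilson_interval(n - k, n)
    assert lo == pytest.approx(1 - mhi, abs=1e-12)
    ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    assert lo == pytest.approx(ref_lo, abs=1e-9)
    assert hi == pytest.approx(ref_hi, abs=1e-9)


def test_wilson_rejects_zero_trials():
    with pytest.raises(ValueError):
        wilson_interval(0, 0)


def test_report_roundtrip_preserves_counts(tmp_path):
    rep = make_report(
        [("c1", 5, "+", 3, 2, "CG"), ("c1", 9, "-", 0, 7, "CHH")]
    )
    path = tmp_path / "rep.tsv"
    write_cytosine_report(rep, path)
    back = read_cytosine_report(path)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), rep.reset_index(drop=True), check_dtype=False
    )
    # 1-based on disk
    first = path.read_text().splitlines()[0].split("\t")
    assert first[1] == "6"
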