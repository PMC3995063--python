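"""Gene contingency tables, Fisher exact tests, FDR, and the group call."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import fisher_exact as scipy_fisher

from apaseq.model import AnnotatedSite, PolyASite
from apaseq.stats import (FDR_THRESHOLD, bh_fdr, build_gene_table,
                          call_apa_gene, count_isoform_ratio, fisher_exact_2xc,
                          sample_pairs)

SAMPLES = ["t1", "t2", "ref"]


def annotated_site(pos, counts, strand="+"):
    return AnnotatedSite(site=PolyASite(chrom="chr1", strand=strand,
                                        position=pos, counts=counts),
                         category="3UTR", gene_id="g")


# --- 10% inclusion rule -----------------------------------------------------

def test_site_included_if_passing_in_one_sample():
    # B is 7.4% of sample1 but 30% of sample2 -> included
    sites = [annotated_site(100, {"t1": 50, "t2": 28}),
             annotated_site(200, {"t1": 4, "t2": 12})]
    table = build_gene_table("g", sites, ["t1", "t2"])
    assert table.site_positions == [100, 200]
    assert table.counts == {"t1": [50, 4], "t2": [28, 12]}


def test_site_below_threshold_everywhere_is_excluded():
    sites = [annotated_site(100, {"t1": 95, "t2": 95}),
             annotated_site(200, {"t1": 5, "t2": 5})]
    table = build_gene_table("g", sites, ["t1", "t2"])
    assert table.site_positions == [100]
    assert table.excluded_positions == [200]
    assert not table.testable


def test_exactly_ten_percent_is_included():
    sites = [annotated_site(100, {"t1": 90}), annotated_site(200, {"t1": 10})]
    table = build_gene_table("g", sites, ["t1"])
    assert table.site_positions == [100, 200]


def test_minus_strand_orders_proximal_first():
    sites = [annotated_site(100, {"t1": 5}, strand="-"),
             annotated_site(300, {"t1": 5}, strand="-")]
    table = build_gene_table("g", sites, ["t1"])
    assert table.site_positions == [300, 100]  # 5'->3' on '-': descending


def test_strict_all_sample_variant():
    sites = [annotated_site(100, {"t1": 50, "t2": 28}),
             annotated_site(200, {"t1": 4, "t2": 12})]
    table = build_gene_table("g", sites, ["t1", "t2"], require_all_samples=True)
    assert table.site_positions == [100]


# --- Fisher exact, 2 x C ----------------------------------------------------

def brute_force_fisher(row_a, row_b, tol=1e-7):
    """Exhaustive enumeration over all 2xC tables with the observed margins
    (independent oracle, plain python)."""
    col_sums = [a + b for a, b in zip(row_a, row_b)]
    r1, n = sum(row_a), sum(col_sums)

    def prob(first_row):
        num = math.prod(comb(c, a, exact=True)
                        for c, a in zip(col_sums, first_row))
        return num / comb(n, r1, exact=True)

    p_obs = prob(row_a)
    total = 0.0
    for first in itertools.product(*(range(c + 1) for c in col_sums)):
        if sum(first) == r1 and prob(first) <= p_obs * (1 + tol):
            total += prob(first)
    return min(1.0, total)


def test_identical_rows_give_p_one():
    assert fisher_exact_2xc([5, 5], [5, 5]) == 1.0


def test_extreme_2x2_table_closed_form():
    # only the two perfectly segregating tables are as extreme: 2 / C(20,10)
    p = fisher_exact_2xc([10, 0], [0, 10])
    assert p == pytest.approx(2 / comb(20, 10, exact=True), abs=1e-12)


def test_2x3_matches_enumeration_oracle():
    assert fisher_exact_2xc([3, 0, 2], [0, 3, 1]) \
        == pytest.approx(brute_force_fisher([3, 0, 2], [0, 3, 1]), abs=1e-10)


@pytest.mark.parametrize("row_a, row_b", [
    ([0, 0], [3, 4]),       # zero row
    ([2, 0], [3, 0]),       # single non-empty column
])
def test_degenerate_tables_return_one(row_a, row_b):
    assert fisher_exact_2xc(row_a, row_b) == 1.0


def test_2x2_matches_hypergeometric_closed_form():
    """50 random small 2x2 tables against scipy's exact two-sided test."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        table = rng.integers(0, 25, size=(2, 2))
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            continue
        expected = scipy_fisher(table).pvalue
        assert fisher_exact_2xc(table[0], table[1]) \
            == pytest.approx(expected, abs=1e-10)


def test_row_swap_symmetry():
    rng = np.random.default_rng(4)
    for _ in range(20):
        a, b = rng.integers(0, 30, size=(2, 3))
        if (a + b).sum() == 0:
            continue
        assert fisher_exact_2xc(a, b) == pytest.approx(fisher_exact_2xc(b, a),
                                                       abs=1e-12)


def test_monte_carlo_fallback_agrees_with_exact():
    """Force the Monte-Carlo path on a table small enough to enumerate."""
    row_a, row_b = [40, 10, 5], [10, 35, 8]
    exact = fisher_exact_2xc(row_a, row_b)
    mc = fisher_exact_2xc(row_a, row_b, max_enumeration=1)
    assert mc == pytest.approx(exact, abs=0.02)
    # fixed seed: reproducible
    assert mc == fisher_exact_2xc(row_a, row_b, max_enumeration=1)


def test_zero_columns_are_ignored():
    assert fisher_exact_2xc([5, 0, 3], [2, 0, 9]) \
        == pytest.approx(fisher_exact_2xc([5, 3], [2, 9]), abs=1e-12)


# --- BH correction ----------------------------------------------------------

@pytest.mark.parametrize("pvals, expected", [
    ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
    ([0.04], [0.04]),
    ([0.05, 1.0], [0.10, 1.0]),
])
def test_bh_step_up_by_hand(pvals, expected):
    assert bh_fdr(pvals) == pytest.approx(expected)


def test_bh_qvalues_dominate_p_and_are_monotone():
    rng = np.random.default_rng(5)
    p = rng.random(40)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# --- group-consistency call -------------------------------------------------

WITHIN, VERSUS = sample_pairs(["a", "b", "c"], "ref")


def make_q(within, versus):
    q = {pair: v for pair, v in zip(WITHIN, within)}
    q.update({pair: v for pair, v in zip(VERSUS, versus)})
    return q


def test_group_call_examples():
    assert call_apa_gene(make_q([0.5, 0.6, 0.7], [0.01, 0.02, 0.03]),
                         WITHIN, VERSUS, FDR_THRESHOLD)
    # tumor group not homogeneous
    assert not call_apa_gene(make_q([0.05, 0.6, 0.7], [0.01, 0.02, 0.03]),
                             WITHIN, VERSUS, FDR_THRESHOLD)
    # one tumor does not differ from the reference
    assert not call_apa_gene(make_q([0.5, 0.6, 0.7], [0.01, 0.02, 0.2]),
                             WITHIN, VERSUS, FDR_THRESHOLD)


def test_missing_pair_is_not_significant():
    q = make_q([0.5, 0.6, 0.7], [0.01, 0.02, 0.03])
    del q[VERSUS[0]]
    assert not call_apa_gene(q, WITHIN, VERSUS, FDR_THRESHOLD)


# --- read-count isoform ratios ----------------------------------------------

def ratio_table():
    sites = [annotated_site(100, {"t1": 30, "t2": 5, "ref": 0}),
             annotated_site(200, {"t1": 10, "t2": 0, "ref": 0})]
    return build_gene_table("g", sites, SAMPLES)


def test_isoform_ratio_arithmetic():
    table = ratio_table()
    assert count_isoform_ratio(table, 100, 200, "t1") == 3.0
    assert count_isoform_ratio(table, 100, 200, "t2") == math.inf
    assert math.isnan(count_isoform_ratio(table, 100, 200, "ref"))
    with pytest.raises(ValueError):
        count_isoform_ratio(table, 100, 999, "t1")
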