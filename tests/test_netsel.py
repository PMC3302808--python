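"""Contingency, permutation and rank-survival selection tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from hapsel.netsel import (
    DegenerateTableError,
    fisher_exact_2x2,
    mann_whitney_exact_p,
    mcdonald_kreitman_feasible,
    permutation_table_test,
    rank_survival_test,
    stratified_table,
    templeton_fisher,
    tip_interior_table,
)
from hapsel.codons import SubstitutionClass
from hapsel.network import MutationRecord


def _fisher_oracle(a, b, c, d):
    """Independent hypergeometric enumeration with exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = math.comb(N, c1)
    def pm(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pm(a)
    total = sum(pm(x) for x in range(lo, hi + 1) if pm(x) <= p_obs)
    return total / denom


def _rec(cls, pos, count=1, region=""):
    return MutationRecord(
        edge=("x", "y"),
        site=1,
        codon_index=0,
        allele_from="A",
        allele_to="C",
        subst_class=cls,
        position_class=pos,
        derived_observed_count=count,
        region=region,
    )


def test_fisher_homogeneous_table():
    assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_small_table_exact_fraction():
    assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)


def test_fisher_matches_enumeration_exhaustively():
    # all 2x2 tables with N <= 12, plus a random sample up to N = 40
    for N in range(2, 13):
        for a in range(N + 1):
            for b in range(N + 1 - a):
                for c in range(N + 1 - a - b):
                    d = N - a - b - c
                    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                        continue
                    assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                        _fisher_oracle(a, b, c, d), rel=1e-9
                    )
    rng = np.random.default_rng(7)
    for _ in range(200):
        t = rng.integers(0, 11, size=4)
        a, b, c, d = map(int, t)
        if (a + b) and (c + d) and (a + c) and (b + d):
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                _fisher_oracle(a, b, c, d), rel=1e-9
            )


def test_fisher_matches_scipy_two_sided():
    rng = np.random.default_rng(3)
    for _ in range(50):
        t = rng.integers(1, 30, size=(2, 2))
        assert fisher_exact_2x2(t) == pytest.approx(
            sps.fisher_exact(t)[1], rel=1e-9
        )


def test_templeton_fisher_from_records():
    recs = (
        [_rec(SubstitutionClass.SYNONYMOUS, "tip")] * 3
        + [_rec(SubstitutionClass.NONSYNONYMOUS, "tip")] * 1
        + [_rec(SubstitutionClass.SYNONYMOUS, "interior")] * 1
        + [_rec(SubstitutionClass.NONSYNONYMOUS, "interior")] * 3
        + [_rec(SubstitutionClass.MULTI_HIT, "tip")]  # ignored
    )
    res = templeton_fisher(recs)
    assert res.table.tolist() == [[3, 1], [1, 3]]
    assert res.p == pytest.approx(34 / 70)


def test_templeton_fisher_degenerate_margin():
    recs = [_rec(SubstitutionClass.SYNONYMOUS, "tip")] * 4
    with pytest.raises(DegenerateTableError):
        templeton_fisher(recs)


def test_tip_interior_table_region_filter():
    recs = [
        _rec(SubstitutionClass.SYNONYMOUS, "tip", region="A"),
        _rec(SubstitutionClass.NONSYNONYMOUS, "interior", region="B"),
    ]
    assert tip_interior_table(recs, region="A").sum() == 1
    strat = stratified_table(recs, ["A", "B"])
    assert strat.shape == (2, 4) and strat.sum() == 2


def test_permutation_single_row_is_one():
    res = permutation_table_test([[3, 4, 5]], n_perm=100, seed=1)
    assert res.p == 1.0


def test_permutation_reproducible_and_seed_sensitive():
    t = [[10, 3], [2, 9]]
    p1 = permutation_table_test(t, n_perm=2000, seed=5).p
    p2 = permutation_table_test(t, n_perm=2000, seed=5).p
    assert p1 == p2


def _exact_perm_p_2x2(table):
    """Exact chi-square-ordering p over the hypergeometric null."""
    t = np.asarray(table)
    r1, c1, N = t[0].sum(), t[:, 0].sum(), t.sum()
    rv = sps.hypergeom(N, r1, c1)
    row_tot, col_tot = t.sum(axis=1), t.sum(axis=0)
    E = np.outer(row_tot, col_tot) / N

    def chi2_of(a):
        tab = np.array([[a, r1 - a], [c1 - a, N - r1 - c1 + a]])
        return ((tab - E) ** 2 / E).sum()

    obs = chi2_of(t[0, 0])
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    return sum(rv.pmf(a) for a in range(lo, hi + 1) if chi2_of(a) >= obs - 1e-9)


def test_permutation_converges_to_exact_on_2x2():
    t = [[8, 2], [3, 7]]
    exact = _exact_perm_p_2x2(t)
    mc = permutation_table_test(t, n_perm=40000, seed=11).p
    assert mc == pytest.approx(exact, abs=3 * math.sqrt(exact * (1 - exact) / 40000) + 1e-4)


def test_permutation_invariant_under_table_symmetry():
    t = np.array([[24, 47, 35, 60], [11, 23, 3, 6]])
    p1 = permutation_table_test(t, n_perm=20000, seed=2).p
    p2 = permutation_table_test(t[:, ::-1], n_perm=20000, seed=3).p
    p3 = permutation_table_test(t[::-1], n_perm=20000, seed=4).p
    se = 3 * math.sqrt(p1 * (1 - p1) / 20000) + 5e-4
    assert abs(p1 - p2) < se and abs(p1 - p3) < se


def test_survival_exact_path_small_groups():
    res = rank_survival_test([1, 2, 3], [4, 5, 6])
    assert res.method == "exact"
    assert res.p == pytest.approx(0.10)
    assert res.medians == (2, 5)


def test_survival_identical_groups_null():
    res = rank_survival_test([5, 7, 5, 7, 9, 9, 5, 7], [5, 7, 5, 7, 9, 9, 5, 7], method="normal")
    assert res.Zc == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_survival_exact_and_edgeworth_agree_on_small_samples(rng):
    # untied data: the Edgeworth tail matches exact enumeration to < 0.01
    for _ in range(25):
        m = int(rng.integers(5, 8))
        n = int(rng.integers(5, 8))
        vals = (rng.permutation(100)[: m + n] + 1).tolist()
        x, y = vals[:m], vals[m:]
        exact = mann_whitney_exact_p(x, y)
        approx = rank_survival_test(x, y, method="edgeworth").p
        assert abs(exact - approx) < 0.01
    # tie-heavy tiny samples: the exact distribution is lumpy; agreement is
    # bounded by the lump size (and auto mode returns the exact p there)
    for _ in range(25):
        m = int(rng.integers(3, 8))
        n = int(rng.integers(3, 8))
        x = rng.integers(1, 30, size=m).tolist()
        y = rng.integers(1, 30, size=n).tolist()
        exact = mann_whitney_exact_p(x, y)
        approx = rank_survival_test(x, y, method="edgeworth").p
        assert abs(exact - approx) < 0.1
        assert rank_survival_test(x, y).p == pytest.approx(exact)  # auto -> exact


def test_survival_min_haplotype_filter_and_empty_group():
    with pytest.raises(ValueError):
        rank_survival_test([1, 2], [5, 6], min_haplotypes=3)
    res = rank_survival_test([1, 3, 4], [2, 5, 6], min_haplotypes=3)
    assert res.syn_counts == [3, 4] and res.nonsyn_counts == [5, 6]


def test_survival_direction_positive_when_nonsyn_larger():
    res = rank_survival_test([3, 4, 5, 6, 7, 8, 9, 10], [11, 12, 13, 14, 15, 16, 17, 30])
    assert res.Zc > 0


def test_mk_gate_reports_no_fixed_differences():
    from hapsel.seqdata import alignment_from_strings

    aln = alignment_from_strings(
        {"a": "ATGAAA", "b": "ATGAAG", "c": "ATGAAA", "d": "ATGAAG"},
        species={"a": "sp1", "b": "sp1", "c": "sp2", "d": "sp2"},
    )
    gate = mcdonald_kreitman_feasible(aln)
    assert not gate["feasible"] and gate["fixed_differences"] == 0
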