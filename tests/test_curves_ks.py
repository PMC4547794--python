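"""Cumulative mismatch curves and the two-sample K-S comparison."""

import math

import numpy as np
import pytest

from phylogeokit import (Alignment, CumulativeCurve, PairwiseDifferenceMatrix,
                         curve_quantile, group_curve, ks_D, ks_critical,
                         ks_test, pairwise_differences)


def curve(vals, label="c"):
    return CumulativeCurve(label, np.array(vals))


def dm_from(names, matrix):
    return PairwiseDifferenceMatrix(names, np.array(matrix))


def test_two_member_group_single_step():
    dm = dm_from(["a", "b"], [[0, 5], [5, 0]])
    c = group_curve(dm, ["a", "b"])
    assert c.m == 1
    assert c.cdf(4) == 0.0
    assert c.cdf(5) == 1.0


def test_hand_counted_cumulative_fractions():
    c = curve([1, 1, 2, 3, 3, 4])
    assert c.cdf(1) == pytest.approx(2 / 6)
    assert c.cdf(2) == pytest.approx(3 / 6)
    assert c.cdf(3) == pytest.approx(5 / 6)
    assert c.cdf(4) == 1.0


def test_group_pair_count_matches_group_size():
    rng = np.random.default_rng(0)
    n = 7
    m = rng.integers(1, 30, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    dm = dm_from([f"s{i}" for i in range(n)], m)
    c = group_curve(dm, dm.names)
    assert c.m == n * (n - 1) // 2


def test_pooled_curve_includes_cross_pairs():
    """A pooled group's curve is recomputed over the union, not averaged."""
    names = ["a1", "a2", "b1", "b2"]
    m = [[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]]
    dm = dm_from(names, m)
    pooled = group_curve(dm, names)
    # within-group pairs both at 1; 4 of 6 pooled pairs are cross at 9
    assert pooled.cdf(1) == pytest.approx(2 / 6)
    avg_within = (group_curve(dm, ["a1", "a2"]).cdf(1)
                  + group_curve(dm, ["b1", "b2"]).cdf(1)) / 2
    assert pooled.cdf(1) != avg_within


def test_singleton_group_rejected():
    dm = dm_from(["a", "b"], [[0, 1], [1, 0]])
    with pytest.raises(ValueError):
        group_curve(dm, ["a"])


def test_D_zero_on_identical_curves():
    c = curve([0, 2, 2, 7])
    D, _ = ks_D(c, curve([0, 2, 2, 7], "other"))
    assert D == 0.0


def test_D_hand_case_with_location():
    D, at = ks_D(curve([0, 1, 2]), curve([2, 3, 4]))
    assert D == pytest.approx(2 / 3)
    assert at[0] == 1.0


def test_D_symmetric_and_self_zero():
    rng = np.random.default_rng(3)
    for _ in range(20):
        c1 = curve(rng.integers(0, 40, size=rng.integers(1, 25)))
        c2 = curve(rng.integers(0, 40, size=rng.integers(1, 25)))
        d12, _ = ks_D(c1, c2)
        d21, _ = ks_D(c2, c1)
        assert d12 == d21
        assert ks_D(c1, c1)[0] == 0.0
        assert 0 <= d12 <= 1


def test_D_invariant_under_monotone_relabeling():
    c1 = curve([0, 1, 2, 5])
    c2 = curve([1, 2, 3, 9])
    base, _ = ks_D(c1, c2)
    f = lambda v: 3 * v ** 2 + 1  # strictly increasing on the support
    mapped, _ = ks_D(curve([f(v) for v in [0, 1, 2, 5]]),
                     curve([f(v) for v in [1, 2, 3, 9]]))
    assert mapped == pytest.approx(base)


def test_critical_value_closed_form():
    # c(0.05) = 1.3581; individuals criterion with n1 = n2 = 10
    da = ks_critical(10, 10, 0.05, "individuals")
    c = math.sqrt(-math.log(0.05 / 2) / 2)
    assert c == pytest.approx(1.3581, abs=1e-4)
    assert da == pytest.approx(c * math.sqrt(0.2))


@pytest.mark.parametrize("criterion", ["pairs", "individuals", "cross",
                                       "pairs_adjusted"])
def test_critical_value_decreases_with_sample_size(criterion):
    prev = None
    for n1 in range(4, 30, 5):
        da = ks_critical(n1, 12, 0.05, criterion)
        if prev is not None:
            assert da < prev
        prev = da


def test_criterion_effective_sizes():
    c = math.sqrt(-math.log(0.05 / 2) / 2)
    assert ks_critical(5, 7, 0.05, "pairs") == pytest.approx(
        c * math.sqrt((10 + 21) / (10 * 21)))
    m = (5 - 1) * (7 - 1) / 2
    assert ks_critical(5, 7, 0.05, "cross") == pytest.approx(
        c * math.sqrt(2 / m))
    assert ks_critical(5, 7, 0.05, "pairs_adjusted") == pytest.approx(
        c * math.sqrt((6 + 15) / (6 * 15)))


def test_unknown_criterion_and_tiny_groups_rejected():
    with pytest.raises(ValueError, match="criterion"):
        ks_critical(5, 5, 0.05, "bogus")
    with pytest.raises(ValueError):
        ks_critical(1, 5, 0.05, "pairs")


def test_ks_test_reports_all_criteria():
    res = ks_test(curve([0, 1, 2], "g1"), curve([2, 3, 4], "g2"), 3, 3)
    assert res.D == pytest.approx(2 / 3)
    crits = {c for c, _ in res.critical}
    assert crits == {"pairs", "individuals", "cross", "pairs_adjusted"}
    assert "K-S" in res.summary()


def test_curve_quantile_hand_case():
    c = curve([1, 1, 2, 3, 3, 4])
    assert curve_quantile(c, 0.5) == 2
    assert curve_quantile(c, 1.0) == 4
    assert curve_quantile(c, 0.01) == 1


def test_single_pair_quantile_is_that_pair():
    c = curve([7])
    for q in (0.1, 0.5, 1.0):
        assert curve_quantile(c, q) == 7


def test_curves_from_alignment_pipeline():
    aln = Alignment(["a1", "a2", "b1", "b2"],
                    ["AAAA", "AAAT", "TTTA", "TTTT"])
    dm = pairwise_differences(aln)
    ca = group_curve(dm, ["a1", "a2"], "A")
    cb = group_curve(dm, ["b1", "b2"], "B")
    D, _ = ks_D(ca, cb)
    assert D == 0.0  # both within-group pairs differ by exactly 1
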