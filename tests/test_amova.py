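"""AMOVA variance decomposition, hand-worked oracle, permutation tests."""

import math

import numpy as np
import pytest

from _oracles import msprime_difference_matrix
from phylogeokit import (Amova, PairwiseDifferenceMatrix,
                         PopulationAssignment, amova,
                         haplotype_frequency_amova, pairwise_phi_st)

NAMES6 = list("abcdef")
D6 = np.array([
    [0, 2, 4, 6, 8, 7],
    [2, 0, 3, 5, 7, 6],
    [4, 3, 0, 4, 6, 5],
    [6, 5, 4, 0, 2, 3],
    [8, 7, 6, 2, 0, 1],
    [7, 6, 5, 3, 1, 0],
])


@pytest.fixture
def two_pop_six():
    dm = PairwiseDifferenceMatrix(NAMES6, D6)
    pa = PopulationAssignment(
        {"a": "P1", "b": "P1", "c": "P1", "d": "P2", "e": "P2", "f": "P2"})
    return dm, pa


def test_six_individual_hand_oracle(two_pop_six):
    """Direct sums-of-squares arithmetic, written out independently."""
    dm, pa = two_pop_six
    d2 = D6.astype(float)  # difference counts enter as squared distances
    N, P = 6, 2
    ssd_total = d2.sum() / (2 * N)
    within = (d2[:3, :3].sum() / (2 * 3)) + (d2[3:, 3:].sum() / (2 * 3))
    ssd_among = ssd_total - within
    msd_within = within / (N - P)
    n_bar = (N - (9 + 9) / N) / (P - 1)
    s2_w = msd_within
    s2_a = (ssd_among / (P - 1) - s2_w) / n_bar
    phi_expected = s2_a / (s2_a + s2_w)

    res = Amova(dm, pa).fit(n_permutations=0)
    tab = res.table.set_index("source")
    assert tab.loc["among populations", "df"] == 1
    assert tab.loc["within populations", "df"] == 4
    assert tab.loc["among populations", "SSD"] == pytest.approx(ssd_among)
    assert tab.loc["within populations", "SSD"] == pytest.approx(within)
    assert tab.loc["among populations", "variance"] == pytest.approx(s2_a)
    assert tab.loc["within populations", "variance"] == pytest.approx(s2_w)
    assert res.phi["phi_ST"] == pytest.approx(phi_expected)


def test_percent_variance_sums_to_100(two_pop_six):
    dm, pa = two_pop_six
    res = Amova(dm, pa).fit(0)
    assert res.table["percent"].iloc[:-1].sum() == pytest.approx(100.0)
    pa4 = PopulationAssignment(
        {"a": "P1", "b": "P1", "c": "P2", "d": "P3", "e": "P3", "f": "P4"})
    res2 = Amova(dm, pa4, groups=[["P1", "P2"], ["P3", "P4"]]).fit(0)
    assert res2.table["percent"].iloc[:-1].sum() == pytest.approx(100.0)
    # variance components sum to the reported total
    assert res2.table["variance"].iloc[:-1].sum() == pytest.approx(
        res2.table["variance"].iloc[-1])
    # sums of squares are additive across strata
    assert res2.table["SSD"].iloc[:-1].sum() == pytest.approx(
        res2.table["SSD"].iloc[-1])


def test_degrees_of_freedom_follow_design():
    """Four populations, no groups: among df = 3, within df = n - 4."""
    rng = np.random.default_rng(2)
    n = 12
    m = rng.integers(1, 20, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    dm = PairwiseDifferenceMatrix([f"s{i}" for i in range(n)], m)
    pa = PopulationAssignment(
        {f"s{i}": f"P{i % 4}" for i in range(n)})
    res = Amova(dm, pa).fit(0)
    tab = res.table.set_index("source")
    assert tab.loc["among populations", "df"] == 3
    assert tab.loc["within populations", "df"] == n - 4


def test_null_phi_st_centered_on_zero():
    """Random splits of one panmictic sample: mean phi_ST ~ 0."""
    names = [f"s{i}" for i in range(16)]
    phis = []
    for i in range(150):
        d = msprime_difference_matrix(16, theta=20.0,
                                      ancestry_seed=3_000 + i,
                                      mutation_seed=4_000 + i)
        dm = PairwiseDifferenceMatrix(names, d)
        rng = np.random.default_rng(6_000 + i)
        half = set(rng.permutation(16)[:8])
        pa = PopulationAssignment(
            {names[j]: ("A" if j in half else "B") for j in range(16)})
        phis.append(Amova(dm, pa).fit(0).phi["phi_ST"])
    phis = np.array(phis)
    se = phis.std(ddof=1) / math.sqrt(len(phis))
    assert abs(phis.mean()) < 3 * se


def test_permutation_p_detects_real_structure():
    names = [f"s{i}" for i in range(8)]
    block = np.full((4, 4), 20)
    d = np.block([[np.ones((4, 4)), block], [block, np.ones((4, 4))]])
    np.fill_diagonal(d, 0)
    dm = PairwiseDifferenceMatrix(names, d.astype(int))
    pa = PopulationAssignment(
        {names[i]: ("A" if i < 4 else "B") for i in range(8)})
    res = amova(dm, pa, n_permutations=500, seed=9)
    assert res.phi["phi_ST"] > 0.8
    assert res.p_values["phi_ST"] < 0.05


def test_permutation_p_stable_across_seeds(two_pop_six):
    dm, pa = two_pop_six
    p1 = Amova(dm, pa).fit(2000, seed=1).p_values["phi_ST"]
    p2 = Amova(dm, pa).fit(2000, seed=2).p_values["phi_ST"]
    se = math.sqrt(p1 * (1 - p1) / 2000)
    assert abs(p1 - p2) < 4 * se + 1e-9


def test_grouped_design_validation(two_pop_six):
    dm, pa = two_pop_six
    with pytest.raises(ValueError, match="partition"):
        Amova(dm, pa, groups=[["P1"], ["P1", "P2"]])
    with pytest.raises(ValueError, match="partition"):
        Amova(dm, pa, groups=[["P1"]])


def test_pairwise_phi_matrix_layout(two_pop_six):
    dm, _ = two_pop_six
    pa = PopulationAssignment(
        {"a": "X", "b": "X", "c": "Y", "d": "Y", "e": "Z", "f": "Z"})
    out = pairwise_phi_st(dm, pa, n_permutations=100, seed=0)
    assert list(out.index) == ["X", "Y", "Z"]
    assert not np.isnan(out.loc["Z", "X"])   # phi in lower triangle
    assert not np.isnan(out.loc["X", "Z"])   # p-value in upper triangle
    assert np.isnan(out.loc["X", "X"])


def test_all_unique_haplotype_mode(two_pop_six):
    """Every individual distinct: the frequency AMOVA degenerates to
    F_ST = 1 with vanishing hierarchical components."""
    dm, pa = two_pop_six
    res = haplotype_frequency_amova(dm, pa, groups=[["P1"], ["P2"]])
    assert res.phi["F_ST"] == 1.0
    assert res.phi["F_SC"] == 0.0
    assert res.phi["F_CT"] == 0.0
    shared = D6.copy()
    shared[0, 1] = shared[1, 0] = 0
    with pytest.raises(ValueError, match="share"):
        haplotype_frequency_amova(
            PairwiseDifferenceMatrix(NAMES6, shared), pa)
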