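"""Neutrality statistics and the sudden-expansion mismatch fit."""

import math

import numpy as np
import pytest

from _oracles import msprime_summary
from phylogeokit import (Alignment, MismatchDistribution,
                         PairwiseDifferenceMatrix, expected_mismatch,
                         fit_expansion, fu_li_D, fu_li_D_star,
                         mismatch_distribution, pairwise_differences,
                         tajimas_D)
from phylogeokit.popgen import external_singletons, segregating_sites


def dm_from(names, matrix):
    return PairwiseDifferenceMatrix(names, np.array(matrix))


# -- mismatch distribution ----------------------------------------------------

def test_identical_sequences_mass_at_zero():
    dm = dm_from(list("abc"), np.zeros((3, 3), int))
    md = mismatch_distribution(dm)
    assert md.histogram() == {0: 3}
    assert md.mean == 0


def test_hand_counted_histogram_and_mean():
    dm = dm_from(list("abc"), [[0, 1, 1], [1, 0, 2], [1, 2, 0]])
    md = mismatch_distribution(dm)
    assert md.histogram() == {1: 2, 2: 1}
    assert md.mean == pytest.approx(4 / 3)
    assert md.n_pairs == 3


def test_singleton_sample_rejected():
    dm = dm_from(list("ab"), [[0, 1], [1, 0]])
    with pytest.raises(ValueError):
        mismatch_distribution(dm, ["a"])


# -- Tajima's D ---------------------------------------------------------------

def test_tajima_zero_when_estimators_agree():
    """k_bar = S/a1 forces the numerator (hence D) to exactly zero."""
    a1 = 1 + 1 / 2 + 1 / 3
    assert tajimas_D(S=3, k_bar=3 / a1, n=4) == 0.0


def test_tajima_matches_independent_constants():
    """Check against the 1989 variance constants coded from scratch."""
    n, S, k = 10, 16, 3.0
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    expected = (k - S / a1) / math.sqrt(
        (c1 / a1) * S + (c2 / (a1 ** 2 + a2)) * S * (S - 1))
    assert tajimas_D(S, k, n) == pytest.approx(expected, rel=1e-12)
    assert expected < 0  # star-like configuration: deficit of diversity


def test_tajima_undefined_cases():
    with pytest.raises(ValueError):
        tajimas_D(0, 1.0, 10)
    with pytest.raises(ValueError):
        tajimas_D(5, 1.0, 3)


def test_tajima_centered_under_neutral_coalescent():
    """Mean D over neutral constant-size simulations sits near zero."""
    vals = []
    for i in range(300):
        S, k = msprime_summary(n=20, theta=10.0, ancestry_seed=10_000 + i,
                               mutation_seed=20_000 + i)
        if S >= 1:
            vals.append(tajimas_D(S, k, 20))
    vals = np.array(vals)
    se = vals.std(ddof=1) / math.sqrt(len(vals))
    assert abs(vals.mean()) < 3 * se + 0.05  # small negative bias of D


# -- Fu & Li ------------------------------------------------------------------

def test_fu_li_zero_at_neutral_singleton_expectation():
    """eta_e = S / a_n zeroes the numerator by construction."""
    n, S = 10, 18
    a_n = sum(1 / i for i in range(1, n))
    assert fu_li_D(S, S / a_n, n) == pytest.approx(0.0, abs=1e-12)


def test_fu_li_constants_against_oracle():
    """n = 5 hand case using independently coded variance constants."""
    n, S, eta_e = 5, 7, 4
    a_n = sum(1 / i for i in range(1, n))
    b_n = sum(1 / i ** 2 for i in range(1, n))
    c_n = 2 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v = 1 + (a_n ** 2 / (b_n + a_n ** 2)) * (c_n - (n + 1) / (n - 1))
    u = a_n - 1 - v
    expected = (S - a_n * eta_e) / math.sqrt(u * S + v * S ** 2)
    assert fu_li_D(S, eta_e, n) == pytest.approx(expected, rel=1e-12)


def test_fu_li_star_neutral_simulations():
    """Neutral simulations: rejection at |D*| > 2 stays near nominal."""
    import msprime

    vals = []
    for i in range(200):
        ts = msprime.sim_ancestry(samples=12, ploidy=1, population_size=1,
                                  sequence_length=1, random_seed=60_000 + i)
        mts = msprime.sim_mutations(ts, rate=4.0, random_seed=70_000 + i,
                                    discrete_genome=False)
        S = mts.num_sites
        if S < 1:
            continue
        G = mts.genotype_matrix()
        freq = (G != 0).sum(axis=1)
        n = G.shape[1]
        singles = int(((freq == 1) | (freq == n - 1)).sum())
        vals.append(fu_li_D_star(S, singles, n))
    vals = np.array(vals)
    rej = np.mean(np.abs(vals) > 2.0)
    assert rej <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / len(vals))


def test_singleton_counting_with_and_without_outgroup():
    aln = Alignment(
        ["i1", "i2", "i3", "i4", "og"],
        ["AAAA", "AAAT", "AACA", "AAAA", "AAAA"],
    )
    ingroup = ["i1", "i2", "i3", "i4"]
    assert segregating_sites(aln, ingroup) == 2
    # both variable sites carry a derived singleton relative to the outgroup
    assert external_singletons(aln, ingroup, outgroup="og") == 2
    assert external_singletons(aln, ingroup, outgroup=None) == 2


# -- expansion fit ------------------------------------------------------------

def test_expected_mismatch_limits():
    f0 = expected_mismatch(0.0, 1.0, 50.0, 40)
    i = np.arange(41)
    geometric = 1.0 ** i / 2.0 ** (i + 1)
    assert f0 == pytest.approx(geometric)
    far = expected_mismatch(500.0, 1.0, 5.0, 40)
    eq5 = 5.0 ** i / 6.0 ** (i + 1)
    assert far == pytest.approx(eq5, abs=1e-6)


def test_expansion_fit_recovers_parameters():
    """Model-generated curve: tau recovered within 1%."""
    probs = expected_mismatch(5.0, 1.0, 100.0, 60)
    fit = fit_expansion(probs)
    assert fit.tau == pytest.approx(5.0, rel=0.01)
    assert fit.theta1 >= fit.theta0


def test_point_mass_at_zero_gives_tau_zero():
    fit = fit_expansion(np.array([1.0]))
    assert fit.tau == pytest.approx(0.0, abs=1e-6)


def test_empty_histogram_rejected():
    with pytest.raises(ValueError):
        fit_expansion(np.zeros(5))


def test_expansion_fit_on_simulated_growth():
    """Coalescent with recent growth yields a unimodal off-origin peak and
    a clearly positive fitted tau."""
    import msprime

    demography = msprime.Demography()
    demography.add_population(initial_size=10_000)
    demography.add_population_parameters_change(
        time=200, initial_size=100, population=0)
    ts = msprime.sim_ancestry(samples=25, ploidy=1, demography=demography,
                              sequence_length=1, random_seed=123)
    mts = msprime.sim_mutations(ts, rate=0.02, random_seed=321,
                                discrete_genome=False)
    G = mts.genotype_matrix()
    n = G.shape[1]
    d = np.zeros((n, n), int)
    for i in range(n):
        d[i] = (G != G[:, [i]]).sum(axis=0)
    np.fill_diagonal(d, 0)
    md = mismatch_distribution(
        PairwiseDifferenceMatrix([f"s{i}" for i in range(n)], d))
    fit = fit_expansion(md)
    assert fit.tau > 0.5
    assert fit.theta1 > fit.theta0
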