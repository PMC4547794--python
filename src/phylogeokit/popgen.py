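"""Mismatch-distribution statistics: Tajima's D, Fu & Li's D, and the
sudden-expansion model fit.

Tajima's D contrasts the mean pairwise difference with the Watterson
estimate S/a1; Fu & Li's D contrasts total polymorphism with mutations on
external branches (singletons).  Both are standardized with the original
variance constants and are strongly negative for star-like genealogies such
as those produced by a recent population expansion.

The sudden-expansion (Rogers-Harpending) model describes a population at
scaled size theta0 that grew instantaneously to theta1 at time tau in the
past (tau in units of pairwise differences, tau = 2ut).  The expected
mismatch probabilities are computed from the pair coalescent in closed form;
see docs/methods.md for the derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import poisson

from .alignment import Alignment, PairwiseDifferenceMatrix

__all__ = [
    "MismatchDistribution",
    "mismatch_distribution",
    "tajimas_D",
    "fu_li_D",
    "fu_li_D_star",
    "segregating_sites",
    "external_singletons",
    "ExpansionFit",
    "SuddenExpansionModel",
    "fit_expansion",
    "expected_mismatch",
]


# ---------------------------------------------------------------------------
# mismatch distribution
# ---------------------------------------------------------------------------

@dataclass
class MismatchDistribution:
    """Histogram of pairwise difference counts over all pairs of a sample."""

    values: np.ndarray  # one entry per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size == 0:
            raise ValueError("empty mismatch distribution")

    @property
    def n_pairs(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def variance(self) -> float:
        return float(self.values.var(ddof=0))

    def histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.values, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def probabilities(self, i_max: int | None = None) -> np.ndarray:
        """Relative frequency of i differences for i = 0..i_max."""
        if i_max is None:
            i_max = int(self.values.max())
        out = np.zeros(i_max + 1)
        for v, c in self.histogram().items():
            if v <= i_max:
                out[v] = c / self.n_pairs
        return out


def mismatch_distribution(dm: PairwiseDifferenceMatrix,
                          members: Sequence[str] | None = None
                          ) -> MismatchDistribution:
    if members is None:
        members = dm.names
    members = list(members)
    if len(members) < 2:
        raise ValueError("mismatch distribution needs >= 2 members")
    return MismatchDistribution(dm.within_pair_values(members))


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------

def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def _harmonic2(n: int) -> float:
    return sum(1.0 / i ** 2 for i in range(1, n))


def tajimas_D(S: int, k_bar: float, n: int) -> float:
    """Tajima (1989) D from segregating sites S, mean pairwise differences
    k_bar, and sample size n."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 1:
        raise ValueError("Tajima's D is undefined for S = 0")
    a1 = _harmonic(n)
    a2 = _harmonic2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (k_bar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _fu_li_cn(n: int, a_n: float) -> float:
    if n == 2:
        return 1.0
    return 2 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))


def fu_li_D(S: int, eta_e: int, n: int) -> float:
    """Fu & Li (1993) D from total mutations S and external-branch
    (outgroup-polarized singleton) mutations eta_e."""
    if n < 4:
        raise ValueError("Fu & Li's D needs n >= 4")
    if S < 1:
        raise ValueError("Fu & Li's D is undefined for S = 0")
    a_n = _harmonic(n)
    b_n = _harmonic2(n)
    c_n = _fu_li_cn(n, a_n)
    v = 1 + (a_n ** 2 / (b_n + a_n ** 2)) * (c_n - (n + 1) / (n - 1))
    u = a_n - 1 - v
    return (S - a_n * eta_e) / math.sqrt(u * S + v * S ** 2)


def fu_li_D_star(S: int, eta_s: int, n: int) -> float:
    """Fu & Li (1993) D* (no outgroup): eta_s counts minor-allele singletons.

    Uses the corrected variance constants (Simonsen, Churchill & Aquadro 1995).
    """
    if n < 4:
        raise ValueError("Fu & Li's D* needs n >= 4")
    if S < 1:
        raise ValueError("Fu & Li's D* is undefined for S = 0")
    a_n = _harmonic(n)
    b_n = _harmonic2(n)
    c_n = _fu_li_cn(n, a_n)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    d_n = (c_n + (n - 2) / (n - 1) ** 2
           + (2 / (n - 1)) * (1.5 - (2 * a_n1 - 3) / (n - 2) - 1.0 / n))
    v = ((n / (n - 1)) ** 2 * b_n + a_n ** 2 * d_n
         - 2 * (n * a_n * (a_n + 1)) / (n - 1) ** 2) / (a_n ** 2 + b_n)
    u = (n / (n - 1)) * (a_n - n / (n - 1)) - v
    return ((n / (n - 1)) * S - a_n * eta_s) / math.sqrt(u * S + v * S ** 2)


def segregating_sites(aln: Alignment, samples: Sequence[str] | None = None
                      ) -> int:
    """Number of variable sites among ``samples`` (unambiguous bases only)."""
    codes = _sample_codes(aln, samples)
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    return int(((counts >= 1).sum(axis=0) >= 2).sum())


def external_singletons(aln: Alignment, samples: Sequence[str],
                        outgroup: str | None = None) -> int:
    """Count singleton mutations among ``samples``.

    With an outgroup, a site counts when exactly one ingroup sequence
    carries a state different from the outgroup's (a derived singleton,
    i.e. a mutation on an external branch).  Without an outgroup the
    unpolarized minor-allele singleton count is returned.
    """
    codes = _sample_codes(aln, samples)
    n = codes.shape[0]
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])  # 4 x L
    if outgroup is None:
        present = counts >= 1
        biallelic_plus = present.sum(axis=0) >= 2
        singleton_state = (counts == 1).any(axis=0)
        # minor allele count 1 at a variable site
        minor_is_one = (counts + (~present) * (n + 1)).min(axis=0) == 1
        return int((biallelic_plus & singleton_state & minor_is_one).sum())
    og = _sample_codes(aln, [outgroup])[0]
    valid_og = og != 255
    derived = (codes != og[None, :]) & (codes != 255) & valid_og[None, :]
    return int((derived.sum(axis=0) == 1).sum())


def _sample_codes(aln: Alignment, samples: Sequence[str] | None) -> np.ndarray:
    if samples is None:
        return aln.codes
    idx = [aln.names.index(s) for s in samples]
    return aln.codes[idx]


# ---------------------------------------------------------------------------
# sudden-expansion model
# ---------------------------------------------------------------------------

def _equilibrium_mismatch(theta: float, i_max: int) -> np.ndarray:
    """Geometric equilibrium mismatch probabilities F_i(theta)."""
    i = np.arange(i_max + 1)
    # theta^i / (theta + 1)^(i+1), computed in logs for stability
    if theta <= 0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log(theta + 1))


def expected_mismatch(tau: float, theta0: float, theta1: float,
                      i_max: int) -> np.ndarray:
    """Expected mismatch probabilities under the sudden-expansion model.

    Exact pair-coalescent form: a random pair either coalesces within the
    post-expansion epoch (rate 1/theta1 per unit tau, mutations Poisson of
    the coalescence time) or survives to the pre-expansion epoch (prob
    exp(-tau/theta1)) and adds a geometric theta0 tail on top of
    Poisson(tau) mutations:

        F_i = Fhat_i(theta1) * P[Poisson(lam * tau) > i]
              + exp(-tau/theta1) * sum_{j<=i} pois(j; tau) * Fhat_{i-j}(theta0)

    with lam = (theta1 + 1)/theta1 and Fhat the geometric equilibrium
    distribution; see docs/methods.md for the derivation.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValueError("tau, theta0, theta1 must be non-negative")
    theta1 = max(theta1, 1e-12)
    lam = (theta1 + 1.0) / theta1
    f1 = _equilibrium_mismatch(theta1, i_max)
    f0 = _equilibrium_mismatch(theta0, i_max)
    i = np.arange(i_max + 1)
    if tau == 0:
        return f0
    # part 1: coalescence within [0, tau) in the current epoch
    part1 = f1 * poisson.sf(i, lam * tau)
    # part 2: survival to the old epoch; Poisson(tau) + geometric(theta0)
    w = poisson.pmf(i, tau) * math.exp(-tau / theta1)
    part2 = np.convolve(w, f0)[: i_max + 1]
    return part1 + part2


@dataclass
class ExpansionFit:
    """Least-squares fit of the sudden-expansion mismatch curve."""

    tau: float
    theta0: float
    theta1: float
    ssd: float  # sum of squared deviations, observed vs expected

    def __post_init__(self) -> None:
        assert self.tau >= 0 and self.theta0 >= 0 and self.theta1 >= 0

    def summary(self) -> str:
        return (
            "Sudden-expansion mismatch fit\n"
            f"  tau     = {self.tau:.4g}  (units of pairwise differences)\n"
            f"  theta0  = {self.theta0:.4g}\n"
            f"  theta1  = {self.theta1:.4g}\n"
            f"  SSD     = {self.ssd:.6g}"
        )

    def to_dict(self) -> dict:
        return {"tau": self.tau, "theta0": self.theta0,
                "theta1": self.theta1, "ssd": self.ssd}


class SuddenExpansionModel:
    """Fit tau, theta0, theta1 to an observed mismatch distribution.

    Deterministic: a fixed multi-start grid feeds a bounded local optimizer
    and the best of all starts is returned.
    """

    def __init__(self, observed) -> None:
        if isinstance(observed, MismatchDistribution):
            probs = observed.probabilities()
        else:
            probs = np.asarray(observed, dtype=float)
        if probs.sum() <= 0:
            raise ValueError("mismatch histogram is empty / all zero")
        self.probs = probs
        self.i_max = len(probs) - 1

    def _objective(self, params: np.ndarray) -> float:
        tau = max(float(params[0]), 0.0)
        theta0 = max(float(params[1]), 0.0)
        theta1 = theta0 + math.exp(min(float(params[2]), 50.0))
        exp_probs = expected_mismatch(tau, theta0, theta1, self.i_max)
        return float(((self.probs - exp_probs) ** 2).sum())

    def fit(self) -> ExpansionFit:
        mean = float(np.arange(self.i_max + 1) @ self.probs)
        tau_grid = sorted({0.01, 0.5, max(mean, 0.02),
                           max(mean / 2, 0.02), max(mean * 1.5, 0.02)})
        theta0_grid = [0.01, 1.0, max(mean / 4, 0.02)]
        dtheta_grid = [math.log(x) for x in (1.0, 10.0, 100.0, 1000.0)]
        best = None
        for t in tau_grid:
            for th0 in theta0_grid:
                for ld in dtheta_grid:
                    res = optimize.minimize(
                        self._objective, x0=np.array([t, th0, ld]),
                        method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-12,
                                 "maxiter": 4000},
                    )
                    x = np.array([max(res.x[0], 0.0), max(res.x[1], 0.0),
                                  res.x[2]])
                    val = self._objective(x)
                    if best is None or val < best[0]:
                        best = (val, x)
        ssd, x = best
        tau, theta0, log_dtheta = x
        theta1 = theta0 + math.exp(min(float(log_dtheta), 50.0))
        return ExpansionFit(tau=float(tau), theta0=float(theta0),
                            theta1=float(theta1), ssd=float(ssd))


def fit_expansion(observed) -> ExpansionFit:
    """Fit the sudden-expansion model to a mismatch distribution (or a raw
    probability/count vector indexed by difference count)."""
    return SuddenExpansionModel(observed).fit()
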