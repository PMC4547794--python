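"""Cumulative pairwise-mismatch curves and their Kolmogorov-Smirnov comparison.

A population's cumulative curve maps a difference count x to the fraction of
within-population sequence pairs differing by at most x sites; it serves as a
continuous proxy for the depth of the population's phylogenetic structure.
Two curves are compared by the classical two-sample K-S statistic D (largest
unsigned vertical offset), evaluated exactly at the step points.

Because the g(g-1)/2 pairs within a group are not mutually independent, the
critical value D_a is computed under several alternative effective-sample-size
criteria, reported side by side:

    pairs           m_i = n_i (n_i - 1) / 2     (anticonservative)
    individuals     m_i = n_i
    cross           m   = (n1 - 1)(n2 - 1) / 2  (one pooled m for both)
    pairs_adjusted  m_i = (n_i - 1)(n_i - 2) / 2

with D_a = c(alpha) * sqrt((m1 + m2) / (m1 * m2)) and
c(alpha) = sqrt(-ln(alpha / 2) / 2) (the Smirnov asymptotic form;
c(0.05) = 1.3581).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import PairwiseDifferenceMatrix

__all__ = [
    "CumulativeCurve",
    "KSResult",
    "group_curve",
    "ks_D",
    "ks_critical",
    "ks_test",
    "curve_quantile",
    "CRITERIA",
]

CRITERIA = ("pairs", "individuals", "cross", "pairs_adjusted")
DEFAULT_ALPHAS = (0.05, 0.01, 0.001)


@dataclass
class CumulativeCurve:
    """Step function: difference value -> cumulative fraction of pairs."""

    label: str
    values: np.ndarray  # sorted multiset of pairwise difference counts

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values))
        if self.values.size == 0:
            raise ValueError("empty curve")

    @property
    def m(self) -> int:
        """Number of pairs contributing to the curve."""
        return int(self.values.size)

    def cdf(self, x) -> np.ndarray:
        """Right-continuous cumulative fraction of pairs <= x."""
        return np.searchsorted(self.values, np.asarray(x), side="right") / self.m

    def step_points(self) -> np.ndarray:
        return np.unique(self.values)

    def quantile(self, q: float) -> float:
        """Smallest difference value whose cumulative fraction is >= q."""
        if not 0 < q <= 1:
            raise ValueError("q must be in (0, 1]")
        idx = int(math.ceil(q * self.m)) - 1
        return float(self.values[idx])

    def as_table(self) -> list[tuple[float, float]]:
        xs = self.step_points()
        return list(zip(xs.tolist(), self.cdf(xs).tolist()))


def group_curve(dm: PairwiseDifferenceMatrix, members: Sequence[str],
                label: str | None = None) -> CumulativeCurve:
    """Cumulative curve over all pairs within ``members``.

    For a pooled group the curve is recomputed over the union, so pairs that
    cross the component samples are included; it is therefore not the average
    of the component curves.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a curve needs a group of at least 2 members")
    values = dm.within_pair_values(members)
    return CumulativeCurve(label or "+".join(members), values)


def ks_D(c1: CumulativeCurve, c2: CumulativeCurve
         ) -> tuple[float, list[float]]:
    """Largest unsigned vertical offset D and the difference values where
    it is attained (exact over the union of step points)."""
    xs = np.union1d(c1.step_points(), c2.step_points())
    gaps = np.abs(c1.cdf(xs) - c2.cdf(xs))
    D = float(gaps.max())
    at = xs[np.isclose(gaps, D)]
    return D, [float(x) for x in at]


def ks_critical(n1: int, n2: int, alpha: float, criterion: str) -> float:
    """Critical value D_a for group sizes n1, n2 under a given criterion."""
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; "
                         f"choose from {CRITERIA}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if criterion == "pairs":
        if n1 < 2 or n2 < 2:
            raise ValueError("pairs criterion needs group sizes >= 2")
        m1, m2 = n1 * (n1 - 1) / 2, n2 * (n2 - 1) / 2
    elif criterion == "individuals":
        if n1 < 1 or n2 < 1:
            raise ValueError("group sizes must be >= 1")
        m1, m2 = n1, n2
    elif criterion == "cross":
        m = (n1 - 1) * (n2 - 1) / 2
        if m < 1:
            raise ValueError("cross criterion needs (n1-1)(n2-1)/2 >= 1")
        m1 = m2 = m
    else:  # pairs_adjusted
        m1, m2 = (n1 - 1) * (n1 - 2) / 2, (n2 - 1) * (n2 - 2) / 2
        if m1 < 1 or m2 < 1:
            raise ValueError("pairs_adjusted criterion needs group sizes >= 3")
    c = math.sqrt(-math.log(alpha / 2) / 2)
    return c * math.sqrt((m1 + m2) / (m1 * m2))


@dataclass
class KSResult:
    """Two-sample K-S comparison of two cumulative mismatch curves."""

    labels: tuple[str, str]
    D: float
    locations: list[float]
    n: tuple[int, int]  # group sizes (individuals)
    critical: dict[tuple[str, float], float]      # (criterion, alpha) -> D_a
    significant: dict[tuple[str, float], bool]

    def __post_init__(self) -> None:
        assert 0.0 <= self.D <= 1.0 + 1e-12

    def summary(self) -> str:
        a, b = self.labels
        lines = [
            f"K-S comparison of cumulative mismatch curves: {a} vs {b}",
            f"  D = {self.D:.4f} at difference value(s) "
            + ", ".join(f"{x:g}" for x in self.locations),
            f"  group sizes n = {self.n[0]}, {self.n[1]}",
            "  criterion        alpha   D_a      significant",
        ]
        for (crit, alpha), da in sorted(self.critical.items()):
            sig = "yes" if self.significant[(crit, alpha)] else "no"
            lines.append(f"  {crit:<15}  {alpha:<6g}  {da:.4f}   {sig}")
        lines.append(
            "  note: within-group pairs are not independent; the 'pairs' "
            "criterion overstates the effective sample size"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "D": self.D,
            "locations": self.locations,
            "n": list(self.n),
            "criteria": [
                {"criterion": crit, "alpha": alpha, "D_a": da,
                 "significant": self.significant[(crit, alpha)]}
                for (crit, alpha), da in sorted(self.critical.items())
            ],
        }


def ks_test(c1: CumulativeCurve, c2: CumulativeCurve, n1: int, n2: int,
            alphas: Sequence[float] = DEFAULT_ALPHAS,
            criteria: Sequence[str] = CRITERIA) -> KSResult:
    """Full K-S comparison: D plus D_a verdicts under every criterion."""
    D, at = ks_D(c1, c2)
    critical: dict[tuple[str, float], float] = {}
    significant: dict[tuple[str, float], bool] = {}
    for crit in criteria:
        for alpha in alphas:
            try:
                da = ks_critical(n1, n2, alpha, crit)
            except ValueError:
                warnings.warn(
                    f"criterion {crit!r} undefined for group sizes "
                    f"{n1}, {n2}; skipped", stacklevel=2)
                continue
            critical[(crit, alpha)] = da
            significant[(crit, alpha)] = D > da
    return KSResult(labels=(c1.label, c2.label), D=D, locations=at,
                    n=(n1, n2), critical=critical, significant=significant)


def curve_quantile(curve: CumulativeCurve, q: float) -> float:
    """Difference value at which the curve first reaches cumulative fraction q."""
    return curve.quantile(q)
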