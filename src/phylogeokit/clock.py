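"""Power-curve molecular clock: T = a * d^b.

Calibration points pair a clock-corrected molecular distance d to an MRCA
with an externally established age T (thousand years).  The power curve is
fitted by ordinary least squares of ln T on ln d, consistent with a
multiplicative error model; node ages are then read off the fitted curve.

The conversion of a mismatch time parameter tau into a distance is left to
the caller (``tau`` or ``tau/2`` conventions both circulate), via the
explicit ``tau_convention`` argument of :func:`age_from_tau`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import LabeledTree

__all__ = ["CalibrationPoint", "ClockFit", "PowerCurveClock",
           "fit_power_curve", "predict_age", "date_tree_nodes",
           "age_from_tau", "read_calibration_points"]


@dataclass(frozen=True)
class CalibrationPoint:
    d: float        # clock-corrected substitutions to the MRCA
    T: float        # age of the MRCA, thousand years (KY)
    label: str = ""

    def __post_init__(self) -> None:
        if self.d <= 0 or self.T <= 0:
            raise ValueError("calibration points need d > 0 and T > 0")


@dataclass
class ClockFit:
    """Fitted power curve T = a * d^b with the log-log regression r^2."""

    a: float
    b: float
    r_squared: float
    points: tuple[CalibrationPoint, ...]

    def __post_init__(self) -> None:
        assert self.a > 0
        assert -1e-12 <= self.r_squared <= 1 + 1e-12

    def predict_age(self, d: float) -> float:
        """Age in KY at distance d; d = 0 maps to age 0 (for b > 0)."""
        if d < 0:
            raise ValueError("distance must be non-negative")
        if d == 0:
            return 0.0
        return self.a * d ** self.b

    def invert(self, T: float) -> float:
        """Distance at which the curve reaches age T."""
        return (T / self.a) ** (1.0 / self.b)

    def summary(self) -> str:
        return (
            "Power-curve molecular clock\n"
            f"  T = {self.a:.4g} * d^{self.b:.4g}   (T in KY)\n"
            f"  r^2 (log-log OLS) = {self.r_squared:.6f}\n"
            f"  calibration points: {len(self.points)}"
        )

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "r_squared": self.r_squared,
                "points": [{"d": p.d, "T": p.T, "label": p.label}
                           for p in self.points]}


class PowerCurveClock:
    """Model object for the calibration regression."""

    def __init__(self, points: Sequence[CalibrationPoint]):
        points = tuple(points)
        if len(points) < 2:
            raise ValueError("need at least 2 calibration points")
        if len({p.d for p in points}) < 2:
            raise ValueError("need at least 2 distinct distances")
        self.points = points

    def fit(self) -> ClockFit:
        x = np.log([p.d for p in self.points])
        y = np.log([p.T for p in self.points])
        res = stats.linregress(x, y)
        return ClockFit(a=float(np.exp(res.intercept)), b=float(res.slope),
                        r_squared=float(res.rvalue ** 2), points=self.points)


def fit_power_curve(points: Sequence[CalibrationPoint]) -> ClockFit:
    return PowerCurveClock(points).fit()


def predict_age(fit: ClockFit, d: float) -> float:
    return fit.predict_age(d)


def age_from_tau(fit: ClockFit, tau: float,
                 tau_convention: str = "tau") -> float:
    """Age for a mismatch time parameter under an explicit convention.

    ``tau_convention`` is "tau" (d = tau) or "tau/2" (d = tau / 2).
    """
    if tau_convention == "tau":
        return fit.predict_age(tau)
    if tau_convention == "tau/2":
        return fit.predict_age(tau / 2.0)
    raise ValueError("tau_convention must be 'tau' or 'tau/2'")


def date_tree_nodes(distances: Mapping[str, float], fit: ClockFit,
                    tree: LabeledTree | None = None) -> pd.DataFrame:
    """Date nodes from per-node distance estimates.

    ``distances`` maps node labels to clock-corrected distances (produced
    upstream by a linearized / clock-constrained tree).  When ``tree`` is
    given with labeled internal nodes, ultrametric consistency is checked:
    a child node deeper than its parent draws a warning.
    """
    for label, d in distances.items():
        if d < 0:
            raise ValueError(f"negative distance for node {label!r}")
    rows = [
        {"node": label, "distance": float(d), "age_ky": fit.predict_age(d)}
        for label, d in distances.items()
    ]
    out = pd.DataFrame(rows)
    if tree is not None:
        _check_monotone(distances, tree)
    return out


def _check_monotone(distances: Mapping[str, float], tree: LabeledTree) -> None:
    dtree = tree.dendropy_tree
    for node in dtree.preorder_internal_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if label not in distances or node.parent_node is None:
            continue
        parent = node.parent_node
        plabel = (parent.taxon.label if parent.taxon is not None
                  else parent.label)
        if plabel in distances and distances[label] > distances[plabel] + 1e-12:
            warnings.warn(
                f"node {label!r} is deeper than its parent {plabel!r}: "
                "input distances are not ultrametric", stacklevel=3)


def read_calibration_points(path) -> list[CalibrationPoint]:
    """TSV with columns d, T and optional label."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "d" not in cols or "t" not in cols:
        raise ValueError("calibration TSV needs columns 'd' and 'T'")
    labels = df[cols["label"]] if "label" in cols else [""] * len(df)
    return [CalibrationPoint(d=float(d), T=float(t), label=str(l))
            for d, t, l in zip(df[cols["d"]], df[cols["t"]], labels)]
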