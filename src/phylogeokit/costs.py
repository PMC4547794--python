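"""Dispersal cost matrices and the biogeographic model builders.

A cost matrix encodes a migration model as the per-event cost of a dispersal
between two populations: the island model charges one unit for any move, a
two-group model charges only for crossing the group boundary (e.g. a
trans-Atlantic event), and a linear stepping-stone model charges one unit per
step along the geographic chain, with optional zero-cost merges collapsing
adjacent populations into one effective deme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CostMatrix", "ModelSpec", "build_cost_matrix"]


class CostMatrix:
    """Symmetric k x k matrix of non-negative dispersal-event costs."""

    def __init__(self, populations: Sequence[str], matrix) -> None:
        populations = list(populations)
        matrix = np.asarray(matrix, dtype=float)
        k = len(populations)
        if len(set(populations)) != k:
            raise ValueError("duplicate population id in cost matrix")
        if matrix.shape != (k, k):
            raise ValueError(f"cost matrix must be {k}x{k}, got {matrix.shape}")
        if np.any(matrix < 0):
            raise ValueError("costs must be non-negative")
        if np.any(np.diag(matrix) != 0):
            raise ValueError("cost matrix diagonal must be zero")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("cost matrix must be symmetric (bidirectional dispersal)")
        self.populations = populations
        self.matrix = matrix
        self._check_triangle()

    def _check_triangle(self) -> None:
        # Triangle inequality is not required for the dispersal DP to be
        # valid, but a violation usually signals a mis-specified model.
        m = self.matrix
        k = len(self.populations)
        for i in range(k):
            for j in range(k):
                via = m[i] + m[:, j]
                if m[i, j] > via.min() + 1e-12:
                    warnings.warn(
                        "cost matrix violates the triangle inequality "
                        f"({self.populations[i]} -> {self.populations[j]}); "
                        "minimum-cost reconstructions remain well defined",
                        stacklevel=3,
                    )
                    return

    @property
    def k(self) -> int:
        return len(self.populations)

    def index_of(self, population: str) -> int:
        return self.populations.index(population)

    def cost(self, a: str, b: str) -> float:
        return float(self.matrix[self.index_of(a), self.index_of(b)])

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "CostMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("cost matrix CSV must be square with matching "
                             "row/column population ids")
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.populations,
                     columns=self.populations).to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CostMatrix(populations={self.populations})"


@dataclass
class ModelSpec:
    """Declarative description of a biogeographic cost model.

    kind:
        "island"          unit cost between any two distinct populations;
        "two_group"       unit cost only across the two groups;
        "stepping_stone"  unit cost per step along ``populations`` order,
                          additive for non-adjacent pairs; ``merges`` lists
                          adjacent pairs collapsed at zero cost.
    """

    kind: str
    populations: list[str]
    groups: tuple[list[str], list[str]] | None = None
    merges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in {"island", "two_group", "stepping_stone"}:
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("every population must appear exactly once")
        if len(self.populations) < 2:
            raise ValueError("need at least 2 populations")
        if self.kind == "two_group":
            if self.groups is None:
                raise ValueError("two_group model needs a group partition")
            g1, g2 = self.groups
            if sorted(list(g1) + list(g2)) != sorted(self.populations):
                raise ValueError("groups must partition the populations")
        if self.merges and self.kind != "stepping_stone":
            raise ValueError("merges apply only to stepping-stone models")


def build_cost_matrix(spec: ModelSpec) -> CostMatrix:
    """Construct the cost matrix for a model specification."""
    pops = spec.populations
    k = len(pops)
    if spec.kind == "island":
        m = np.ones((k, k)) - np.eye(k)
    elif spec.kind == "two_group":
        g1 = set(spec.groups[0])
        m = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if (pops[i] in g1) != (pops[j] in g1):
                    m[i, j] = 1.0
    else:  # stepping_stone
        block = _merge_blocks(pops, spec.merges)
        m = np.abs(block[:, None] - block[None, :]).astype(float)
    return CostMatrix(pops, m)


def _merge_blocks(pops: list[str], merges: list[tuple[str, str]]) -> np.ndarray:
    """Block position of each population along the chain after zero-cost merges."""
    pos = {p: i for i, p in enumerate(pops)}
    merged_with_next = [False] * (len(pops) - 1)
    for a, b in merges:
        if a not in pos or b not in pos:
            raise ValueError(f"merge names unknown population: {(a, b)!r}")
        i, j = sorted((pos[a], pos[b]))
        if j - i != 1:
            raise ValueError(
                f"can only merge populations adjacent in the order: {(a, b)!r}"
            )
        merged_with_next[i] = True
    block = np.zeros(len(pops), dtype=np.int64)
    for i in range(1, len(pops)):
        block[i] = block[i - 1] + (0 if merged_with_next[i - 1] else 1)
    return block
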