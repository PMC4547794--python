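"""Tip -> population assignments.

The assignment is the randomized quantity in the Monte Carlo test: the tree
topology stays fixed while labels are permuted among tips preserving the
per-population counts.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PopulationAssignment", "read_population_map"]


class PopulationAssignment:
    """Mapping tip name -> population id with an explicit population order.

    The order matters: stepping-stone cost matrices are defined along it.
    By default it is first-appearance order in the input.
    """

    def __init__(self, mapping: Mapping[str, str],
                 populations: Sequence[str] | None = None):
        mapping = dict(mapping)
        for tip, pop in mapping.items():
            if pop is None or str(pop) == "":
                raise ValueError(f"empty population id for tip {tip!r}")
        seen_order: list[str] = []
        for pop in mapping.values():
            if pop not in seen_order:
                seen_order.append(pop)
        if populations is None:
            populations = seen_order
        else:
            populations = list(populations)
            if set(populations) != set(seen_order):
                raise ValueError(
                    "explicit population order must contain exactly the "
                    "populations present in the mapping"
                )
        self.mapping: dict[str, str] = mapping
        self.populations: list[str] = populations

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, populations: Sequence[str] | None = None
                 ) -> "PopulationAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         comment="#", skip_blank_lines=True)
        if df.shape[1] < 2:
            raise ValueError("population map needs two columns: tip, population")
        df = df.iloc[:, :2]
        df.columns = ["tip", "population"]
        # tolerate an optional header row
        if list(df.iloc[0]) == ["tip", "population"]:
            df = df.iloc[1:]
        dup = df["tip"][df["tip"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate tip in population map: {dup.iloc[0]!r}")
        if df["population"].isna().any() or (df["population"] == "").any():
            raise ValueError("empty population id in population map")
        mapping = dict(zip(df["tip"], df["population"]))
        return cls(mapping, populations)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"tip": list(self.mapping), "population": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False, header=False)

    # -- queries ------------------------------------------------------------

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.mapping.values())
        return {p: c[p] for p in self.populations}

    @property
    def n_tips(self) -> int:
        return len(self.mapping)

    def members(self, population: str) -> list[str]:
        return [t for t, p in self.mapping.items() if p == population]

    def validate_tips(self, tip_names: Sequence[str]) -> None:
        """Check the assignment covers exactly the given tips."""
        tips = set(tip_names)
        extra = set(self.mapping) - tips
        if extra:
            raise ValueError(
                f"population map names a tip not in the tree: {sorted(extra)[0]!r}"
            )
        missing = tips - set(self.mapping)
        if missing:
            raise ValueError(f"unlabeled tip: {sorted(missing)[0]!r}")

    def label_indices(self, tip_order: Sequence[str],
                      population_order: Sequence[str] | None = None
                      ) -> np.ndarray:
        """Integer label per tip, in the given tip order.

        Indices refer to ``population_order`` (defaults to this assignment's
        own order), so they can be aligned with a cost matrix.
        """
        pops = list(population_order) if population_order is not None \
            else self.populations
        idx = {p: i for i, p in enumerate(pops)}
        try:
            return np.array([idx[self.mapping[t]] for t in tip_order],
                            dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"no label/population for {exc.args[0]!r}") from exc


def read_population_map(path, populations: Sequence[str] | None = None
                        ) -> PopulationAssignment:
    """Read a two-column TSV (tip, population)."""
    return PopulationAssignment.from_tsv(path, populations)
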