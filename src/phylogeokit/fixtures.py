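"""Deterministic generators for test inputs.

Three families of fixtures:

* the five frozen 16-tip toy trees illustrating how dispersal length L
  shrinks as phylogeographic structure strengthens (models A-E, four areas
  r / o / g / b);
* random labeled trees and clade-structured labelings with a tunable number
  of label swaps, for property tests and power studies of the Monte Carlo
  test;
* Jukes-Cantor sequence simulation along a tree with branch lengths, for
  the mismatch-curve and popgen statistics.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .alignment import Alignment
from .populations import PopulationAssignment
from .tree import LabeledTree

__all__ = [
    "FIG7_MODELS",
    "make_fig7",
    "random_tree",
    "clade_tree",
    "random_structured_labels",
    "simulate_alignment",
]

# Frozen topologies.  Tip prefixes are the area labels; model D places one
# blue-area individual inside the green clade ("minimal exchange"), so its
# area counts are r=4, o=4, g=3, b=5 while all other models have 4 of each.
FIG7_NEWICK: dict[str, str] = {
    "A": "((((r1,r2),(r3,r4)),((o1,o2),(o3,o4))),"
         "(((g1,g2),(g3,g4)),((b1,b2),(b3,b4))));",
    "B": "((((r1,o1),(g1,b1)),((r2,o2),(g2,b2))),"
         "(((r3,o3),(g3,b3)),((r4,o4),(g4,b4))));",
    "C": "((((r1,o1),(r2,o2)),((r3,o3),(r4,o4))),"
         "(((g1,b1),(g2,b2)),((g3,b3),(g4,b4))));",
    "D": "((((r1,o1),(r2,o2)),((r3,o3),(r4,o4))),"
         "(((g1,g2),(g3,b1)),((b2,b3),(b4,b5))));",
    "E": "((((r1,o1),(r2,o2)),((r3,o3),(r4,o4))),"
         "(((g1,g2),(g3,g4)),((b1,b2),(b3,b4))));",
}

FIG7_MODELS = tuple(FIG7_NEWICK)

# Expected minimum dispersal costs under the unit-cost island matrix.
FIG7_ISLAND_L: dict[str, int] = {"A": 3, "B": 12, "C": 9, "D": 7, "E": 6}


def make_fig7(model: str) -> tuple[LabeledTree, PopulationAssignment]:
    """One of the five frozen 16-tip toy trees with its area labeling."""
    if model not in FIG7_NEWICK:
        raise ValueError(f"model must be one of {FIG7_MODELS}, got {model!r}")
    tree = LabeledTree.from_newick(FIG7_NEWICK[model])
    mapping = {tip: tip[0] for tip in tree.tip_names}
    return tree, PopulationAssignment(mapping, populations=list("rogb"))


def random_tree(n_tips: int, seed=None, branch_lengths: bool = False,
                mean_branch_length: float = 0.1) -> LabeledTree:
    """Random binary tree with tips t1..tn, by random sequential joining."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    def bl() -> str:
        if not branch_lengths:
            return ""
        return f":{rng.exponential(mean_branch_length):.6f}"

    nodes = [f"t{i + 1}{bl()}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}){bl()}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return LabeledTree.from_newick(nodes[0] + ";")


def clade_tree(counts: Mapping[str, int], seed=None,
               branch_lengths: bool = False) -> LabeledTree:
    """Tree whose tips form one monophyletic clade per population.

    Tips are named <pop><index>; clades are joined in a ladder, so a
    perfect clade-per-population labeling exists by construction.
    """
    rng = np.random.default_rng(seed)
    clades = []
    for pop, c in counts.items():
        if c < 1:
            raise ValueError("counts must be >= 1")
        tips = [f"{pop}{i + 1}" for i in range(c)]
        sub = tips[0]
        for t in tips[1:]:
            sub = f"({sub},{t})"
        clades.append(sub)
    order = rng.permutation(len(clades))
    tree = clades[order[0]]
    for k in order[1:]:
        tree = f"({tree},{clades[k]})"
    return LabeledTree.from_newick(tree + ";")


def random_structured_labels(tree: LabeledTree, counts: Mapping[str, int],
                             n_swaps: int, seed=None
                             ) -> PopulationAssignment:
    """Perfect clade-per-population labeling perturbed by label swaps.

    Starts from a labeling in which every population is a monophyletic
    clade of the required size (error if the tree admits none), then
    applies ``n_swaps`` random transpositions of tip labels.  ``n_swaps``
    tunes how much phylogeographic structure survives.
    """
    counts = dict(counts)
    if sum(counts.values()) != tree.n_tips:
        raise ValueError("counts must sum to the number of tips")
    clades = _exact_clade_cover(tree, sorted(counts.values(), reverse=True))
    rng = np.random.default_rng(seed)
    unused = dict(counts)
    mapping: dict[str, str] = {}
    for clade_tips in clades:
        pop = next(p for p, c in unused.items() if c == len(clade_tips))
        del unused[pop]
        for t in clade_tips:
            mapping[t] = pop
    tips = tree.tip_names
    labels = [mapping[t] for t in tips]
    for _ in range(n_swaps):
        i, j = rng.choice(len(tips), size=2, replace=False)
        labels[i], labels[j] = labels[j], labels[i]
    return PopulationAssignment(dict(zip(tips, labels)),
                                populations=list(counts))


def _exact_clade_cover(tree: LabeledTree, sizes: list[int]
                       ) -> list[list[str]]:
    """Greedy exact cover of the tips by disjoint clades of given sizes."""
    children, tip_index, _ = tree.postorder_structure()
    idx_to_tip = {i: t for t, i in tip_index.items()}
    clade_tips: list[list[str]] = [None] * len(children)
    for v, ch in enumerate(children):
        if not ch:
            clade_tips[v] = [idx_to_tip[v]]
        else:
            clade_tips[v] = [t for c in ch for t in clade_tips[c]]
    taken: set[str] = set()
    cover: list[list[str]] = []
    # largest needed size first, so a big clade is never consumed piecemeal
    # by one of its own subclades matching a smaller count
    by_size = sorted(range(len(children)), key=lambda v: -len(clade_tips[v]))
    for size in sorted(sizes, reverse=True):
        for v in by_size:
            tips = clade_tips[v]
            if len(tips) == size and not (set(tips) & taken):
                cover.append(tips)
                taken.update(tips)
                break
        else:
            raise ValueError(
                "tree admits no clade-per-population labeling for these counts"
            )
    return cover


_BASES = np.arange(4, dtype=np.uint8)
_BASE_CHARS = "ACGT"


def simulate_alignment(tree: LabeledTree, seq_length: int, seed=None
                       ) -> Alignment:
    """Jukes-Cantor simulation of sequences along a tree.

    The root sequence is uniform over A/C/G/T; on each branch, mutations
    are placed as a Poisson process with mean (branch length x seq_length)
    at uniformly random sites, each substituting one of the three other
    bases uniformly.  Branch lengths are expected substitutions per site.
    """
    if seq_length < 1:
        raise ValueError("sequence length must be positive")
    children, tip_index, edge_lengths = tree.postorder_structure()
    for v, bl in enumerate(edge_lengths[:-1]):  # root edge may be None
        if bl is not None and bl < 0:
            raise ValueError("negative branch length")
    rng = np.random.default_rng(seed)
    n_nodes = len(children)
    root = n_nodes - 1
    seqs: dict[int, np.ndarray] = {
        root: rng.integers(0, 4, size=seq_length, dtype=np.uint8)
    }
    # parents in preorder so a child's parent sequence always exists
    for parent, child in tree.preorder_edges():
        bl = edge_lengths[child]
        if bl is None:
            raise ValueError("simulation requires branch lengths on all edges")
        seq = seqs[parent].copy()
        n_mut = rng.poisson(bl * seq_length)
        for _ in range(n_mut):
            site = rng.integers(seq_length)
            old = seq[site]
            seq[site] = (old + 1 + rng.integers(3)) % 4
        seqs[child] = seq
    names = tree.tip_names
    strings = [
        "".join(_BASE_CHARS[b] for b in seqs[tip_index[name]])
        for name in names
    ]
    return Alignment(names, strings)
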