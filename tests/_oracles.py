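"""Independent oracles used by the test suite.

These deliberately avoid the library's dynamic-programming and analytic
code paths: minimum dispersal costs are found by exhaustive enumeration of
internal-node state assignments, the island-model special case by Fitch's
set method, and coalescent data come from msprime.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_min_cost(tree, assignment, costs) -> float:
    """Minimize total edge cost over every internal state assignment."""
    children, tip_index, _ = tree.postorder_structure()
    k = costs.k
    tip_state = {}
    for name in tree.tip_names:
        tip_state[tip_index[name]] = costs.index_of(assignment.mapping[name])
    internal = [v for v, ch in enumerate(children) if ch]
    edges = [(v, c) for v in internal for c in children[v]]
    C = costs.matrix
    best = np.inf
    for combo in itertools.product(range(k), repeat=len(internal)):
        state = dict(tip_state)
        state.update(zip(internal, combo))
        total = sum(C[state[p], state[c]] for p, c in edges)
        best = min(best, total)
    return float(best)


def fitch_count(tree, assignment) -> int:
    """Fitch small-parsimony change count (unit-cost island oracle)."""
    children, tip_index, _ = tree.postorder_structure()
    state_sets: list[set] = [None] * len(children)
    for name in tree.tip_names:
        state_sets[tip_index[name]] = {assignment.mapping[name]}
    changes = 0
    for v, ch in enumerate(children):
        if not ch:
            continue
        inter = set.intersection(*(state_sets[c] for c in ch))
        # generalized Fitch for polytomies: greedy majority-state union
        if inter:
            state_sets[v] = inter
        else:
            from collections import Counter
            counts = Counter()
            for c in ch:
                counts.update(state_sets[c])
            top = counts.most_common(1)[0][1]
            state_sets[v] = {s for s, c in counts.items() if c == top}
            changes += len(ch) - top
    return changes


def msprime_difference_matrix(n: int, theta: float, ancestry_seed: int,
                              mutation_seed: int) -> np.ndarray:
    """Pairwise difference counts for a neutral panmictic coalescent sample."""
    import msprime

    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1,
                              sequence_length=1, random_seed=ancestry_seed)
    mts = msprime.sim_mutations(ts, rate=theta / 2.0,
                                random_seed=mutation_seed,
                                discrete_genome=False)
    G = mts.genotype_matrix()
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d[i] = (G != G[:, [i]]).sum(axis=0)
    np.fill_diagonal(d, 0)
    return d


def msprime_summary(n: int, theta: float, ancestry_seed: int,
                    mutation_seed: int) -> tuple[int, float]:
    """(segregating sites, mean pairwise differences) for a neutral sample."""
    import msprime

    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1,
                              sequence_length=1, random_seed=ancestry_seed)
    mts = msprime.sim_mutations(ts, rate=theta / 2.0,
                                random_seed=mutation_seed,
                                discrete_genome=False)
    return int(mts.num_sites), float(mts.diversity(span_normalise=False))
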