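"""Full-study integration run (optional; requires user-supplied data).

The published analyses this package reimplements were computed on 53
complete harp seal mitogenome coding regions (GenBank KP942529-KP942581)
and the neighbor-joining topology estimated from them.  Neither is bundled
here: the alignment must be downloaded and aligned, and the tree rebuilt,
by the user.  Given those two files plus the population map, this entry
point reruns every engine end to end.
"""

from __future__ import annotations

import os

from .alignment import Alignment, pairwise_differences, site_counts
from .amova import Amova
from .costs import ModelSpec, build_cost_matrix
from .curves import group_curve, ks_test
from .montecarlo import DispersalRandomizationTest
from .populations import PopulationAssignment
from .tree import LabeledTree

__all__ = ["run_full_study", "FullStudyDataMissing"]


class FullStudyDataMissing(FileNotFoundError):
    """Raised when the user has not supplied the full-study input files."""


def run_full_study(alignment_fasta: str, tree_newick: str,
                   population_tsv: str, n_reps: int = 10_000,
                   seed: int | None = None) -> dict:
    """Recompute the headline analyses from user-supplied study data.

    Returns a dict with alignment summaries, Monte Carlo results for the
    island / trans-Atlantic / stepping-stone models, the AMOVA models and
    the between-population K-S comparisons.
    """
    for path in (alignment_fasta, tree_newick, population_tsv):
        if not os.path.exists(path):
            raise FullStudyDataMissing(
                f"{path} not found: the full-study inputs (aligned "
                "mitogenomes, tree, population map) must be supplied by "
                "the user; see this module's docstring"
            )
    aln = Alignment.from_fasta(alignment_fasta)
    tree = LabeledTree.from_newick_file(tree_newick)
    pops = PopulationAssignment.from_tsv(population_tsv)
    dm = pairwise_differences(aln)
    sites = site_counts(aln)
    order = pops.populations
    models = {
        "island": ModelSpec("island", order),
        "two_group": ModelSpec("two_group", order,
                               groups=(order[:2], order[2:])),
        "stepping_stone_4": ModelSpec("stepping_stone", order),
        "stepping_stone_3": ModelSpec("stepping_stone", order,
                                      merges=[(order[0], order[1])]),
    }
    mc = {
        name: DispersalRandomizationTest(
            tree, pops, build_cost_matrix(spec)).fit(n_reps, seed)
        for name, spec in models.items()
    }
    amova_results = {
        "four_island": Amova(dm, pops).fit(n_reps, seed),
    }
    curves = {p: group_curve(dm, pops.members(p), p) for p in order
              if len(pops.members(p)) >= 2}
    ks = {}
    names = list(curves)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ks[f"{a}|{b}"] = ks_test(curves[a], curves[b],
                                     len(pops.members(a)),
                                     len(pops.members(b)))
    return {"site_counts": sites, "difference_matrix": dm,
            "mc": mc, "amova": amova_results, "ks": ks}
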