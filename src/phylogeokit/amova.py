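"""Distance-based hierarchical analysis of molecular variance (AMOVA).

Pairwise nucleotide difference counts enter as squared Euclidean distances
(the haplotypic-distance convention), sums of squares are partitioned across
the nested design (groups / populations within groups / individuals within
populations), and variance components are obtained from the standard nested
ANOVA expectations with unequal sample sizes.  Fixation indices:

    phi_ST = (s2_a + s2_b) / s2_total     total differentiation
    phi_SC = s2_b / (s2_b + s2_c)         among populations within groups
    phi_CT = s2_a / s2_total              among groups

where a = among groups, b = among populations within groups, c = within
populations.  Significance is assessed by permutation: individuals among
populations (phi_ST), individuals among populations within groups (phi_SC),
and whole populations among groups (phi_CT); one-tailed
p = #(permuted >= observed) / n_permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import PairwiseDifferenceMatrix
from .populations import PopulationAssignment

__all__ = ["Amova", "AmovaResult", "amova", "pairwise_phi_st",
           "haplotype_frequency_amova"]


def _ssd_within_pops(d2: np.ndarray, labels: np.ndarray, n_pops: int) -> float:
    """SSD within populations = sum_p (1/n_p) sum_{i<j in p} d2_ij."""
    total = 0.0
    for p in range(n_pops):
        idx = np.flatnonzero(labels == p)
        if idx.size > 1:
            total += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def _ssd_total(d2: np.ndarray) -> float:
    return d2.sum() / (2.0 * d2.shape[0])


@dataclass
class AmovaResult:
    """AMOVA variance decomposition and permutation verdicts."""

    design: str
    table: pd.DataFrame          # source, df, SSD, variance, percent
    phi: dict[str, float]
    p_values: dict[str, float | None]
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        lines = [f"AMOVA ({self.design})", self.table.to_string(index=False)]
        lines.append("fixation indices:")
        for name, value in self.phi.items():
            p = self.p_values.get(name)
            if p is None:
                ptxt = ""
            elif p == 0:
                ptxt = f"  p < {1.0 / max(self.n_permutations, 1):g}"
            else:
                ptxt = f"  p = {p:.4f}"
            lines.append(f"  {name} = {value: .4f}{ptxt}")
        if self.n_permutations:
            lines.append(f"permutations: {self.n_permutations} "
                         f"(seed {self.seed})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "table": self.table.to_dict(orient="records"),
            "phi": self.phi,
            "p_values": self.p_values,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


class Amova:
    """Model object: a distance matrix with a (possibly grouped) design."""

    def __init__(self, dm: PairwiseDifferenceMatrix,
                 assignment: PopulationAssignment,
                 groups: Sequence[Sequence[str]] | None = None):
        assignment.validate_tips(dm.names)
        counts = assignment.counts
        if any(c == 0 for c in counts.values()):
            raise ValueError("every population needs at least one member")
        if len(counts) < 2:
            raise ValueError("AMOVA needs at least 2 populations")
        if groups is not None:
            flat = [p for g in groups for p in g]
            if sorted(flat) != sorted(assignment.populations):
                raise ValueError("groups must partition the populations")
            if len(groups) < 2:
                raise ValueError("grouped AMOVA needs at least 2 groups")
        self.dm = dm
        self.assignment = assignment
        self.groups = [list(g) for g in groups] if groups is not None else None
        self.pops = assignment.populations
        # squared-distance convention: difference counts ARE the d^2 values
        self.d2 = dm.values.astype(float)
        self.labels = assignment.label_indices(dm.names, self.pops)
        self.pop_sizes = np.bincount(self.labels, minlength=len(self.pops))
        self.N = len(dm.names)

    # -- statistic machinery -------------------------------------------------

    def _components_one_level(self, labels: np.ndarray):
        P = len(self.pops)
        N = self.N
        ssd_t = _ssd_total(self.d2)
        ssd_w = _ssd_within_pops(self.d2, labels, P)
        ssd_a = ssd_t - ssd_w
        df_a, df_w = P - 1, N - P
        msd_w = ssd_w / df_w
        sizes = np.bincount(labels, minlength=P)
        n_bar = (N - (sizes ** 2).sum() / N) / df_a
        s2_c = msd_w
        s2_b = (ssd_a / df_a - s2_c) / n_bar
        return ssd_t, ssd_a, ssd_w, df_a, df_w, s2_b, s2_c

    def _components_nested(self, labels: np.ndarray,
                           pop_group: np.ndarray):
        """Variance components for the two-level design.

        ``pop_group[p]`` is the group index of population p.
        """
        P = len(self.pops)
        G = int(pop_group.max()) + 1
        N = self.N
        group_of_ind = pop_group[labels]
        ssd_t = _ssd_total(self.d2)
        ssd_wp = _ssd_within_pops(self.d2, labels, P)
        # SSD within groups (individuals pooled by group)
        ssd_wg = 0.0
        for g in range(G):
            idx = np.flatnonzero(group_of_ind == g)
            ssd_wg += self.d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        ssd_ag = ssd_t - ssd_wg
        ssd_apwg = ssd_wg - ssd_wp
        df_ag = G - 1
        df_apwg = P - G
        df_wp = N - P
        sizes = np.bincount(labels, minlength=P).astype(float)
        group_sizes = np.array([sizes[pop_group == g].sum() for g in range(G)])
        sum_n2_by_group = np.array(
            [(sizes[pop_group == g] ** 2).sum() for g in range(G)]
        )
        n = (N - (sum_n2_by_group / group_sizes).sum()) / df_apwg
        n_p = ((sum_n2_by_group / group_sizes).sum()
               - (sizes ** 2).sum() / N) / df_ag
        n_pp = (N - (group_sizes ** 2).sum() / N) / df_ag
        s2_c = ssd_wp / df_wp
        s2_b = (ssd_apwg / df_apwg - s2_c) / n
        s2_a = (ssd_ag / df_ag - s2_c - n_p * s2_b) / n_pp
        return (ssd_t, ssd_ag, ssd_apwg, ssd_wp,
                df_ag, df_apwg, df_wp, s2_a, s2_b, s2_c)

    def _phi_st_one_level(self, labels: np.ndarray) -> float:
        *_, s2_b, s2_c = self._components_one_level(labels)
        return s2_b / (s2_b + s2_c)

    # -- fitting -------------------------------------------------------------

    def fit(self, n_permutations: int = 10_000,
            seed: int | None = None) -> AmovaResult:
        rng = np.random.default_rng(seed)
        if self.groups is None:
            return self._fit_one_level(n_permutations, rng, seed)
        return self._fit_nested(n_permutations, rng, seed)

    def _fit_one_level(self, n_perm, rng, seed) -> AmovaResult:
        labels = self.labels
        (ssd_t, ssd_a, ssd_w, df_a, df_w,
         s2_b, s2_c) = self._components_one_level(labels)
        total_var = s2_b + s2_c
        phi_st = s2_b / total_var
        table = pd.DataFrame({
            "source": ["among populations", "within populations", "total"],
            "df": [df_a, df_w, df_a + df_w],
            "SSD": [ssd_a, ssd_w, ssd_t],
            "variance": [s2_b, s2_c, total_var],
            "percent": [100 * s2_b / total_var, 100 * s2_c / total_var, 100.0],
        })
        p = None
        if n_perm:
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(labels)
                if self._phi_st_one_level(perm) >= phi_st - 1e-12:
                    exceed += 1
            p = exceed / n_perm
        return AmovaResult(
            design=f"{len(self.pops)} populations, no groups",
            table=table, phi={"phi_ST": float(phi_st)},
            p_values={"phi_ST": p}, n_permutations=n_perm, seed=seed,
        )

    def _fit_nested(self, n_perm, rng, seed) -> AmovaResult:
        pop_group = np.empty(len(self.pops), dtype=np.int64)
        for g, members in enumerate(self.groups):
            for p in members:
                pop_group[self.pops.index(p)] = g
        (ssd_t, ssd_ag, ssd_apwg, ssd_wp, df_ag, df_apwg, df_wp,
         s2_a, s2_b, s2_c) = self._components_nested(self.labels, pop_group)
        total_var = s2_a + s2_b + s2_c
        phi = {
            "phi_ST": float((s2_a + s2_b) / total_var),
            "phi_SC": float(s2_b / (s2_b + s2_c)),
            "phi_CT": float(s2_a / total_var),
        }
        table = pd.DataFrame({
            "source": ["among groups", "among populations within groups",
                       "within populations", "total"],
            "df": [df_ag, df_apwg, df_wp, df_ag + df_apwg + df_wp],
            "SSD": [ssd_ag, ssd_apwg, ssd_wp, ssd_t],
            "variance": [s2_a, s2_b, s2_c, total_var],
            "percent": [100 * s2_a / total_var, 100 * s2_b / total_var,
                        100 * s2_c / total_var, 100.0],
        })
        p_values: dict[str, float | None] = dict.fromkeys(phi)
        if n_perm:
            p_values["phi_ST"] = self._perm_phi_st_nested(
                phi["phi_ST"], pop_group, n_perm, rng)
            p_values["phi_SC"] = self._perm_phi_sc(
                phi["phi_SC"], pop_group, n_perm, rng)
            p_values["phi_CT"] = self._perm_phi_ct(
                phi["phi_CT"], pop_group, n_perm, rng)
        design = " | ".join("(" + " ".join(g) + ")" for g in self.groups)
        return AmovaResult(design=f"groups {design}", table=table, phi=phi,
                           p_values=p_values, n_permutations=n_perm, seed=seed)

    def _perm_phi_st_nested(self, observed, pop_group, n_perm, rng) -> float:
        exceed = 0
        for _ in range(n_perm):
            labels = rng.permutation(self.labels)
            *_, s2_a, s2_b, s2_c = self._components_nested(labels, pop_group)
            if (s2_a + s2_b) / (s2_a + s2_b + s2_c) >= observed - 1e-12:
                exceed += 1
        return exceed / n_perm

    def _perm_phi_sc(self, observed, pop_group, n_perm, rng) -> float:
        group_of_ind = pop_group[self.labels]
        exceed = 0
        for _ in range(n_perm):
            labels = self.labels.copy()
            for g in range(int(pop_group.max()) + 1):
                idx = np.flatnonzero(group_of_ind == g)
                labels[idx] = rng.permutation(labels[idx])
            comps = self._components_nested(labels, pop_group)
            s2_b, s2_c = comps[-2], comps[-1]
            if s2_b / (s2_b + s2_c) >= observed - 1e-12:
                exceed += 1
        return exceed / n_perm

    def _perm_phi_ct(self, observed, pop_group, n_perm, rng) -> float:
        exceed = 0
        for _ in range(n_perm):
            perm_group = pop_group[rng.permutation(len(pop_group))]
            comps = self._components_nested(self.labels, perm_group)
            s2_a, s2_b, s2_c = comps[-3], comps[-2], comps[-1]
            if s2_a / (s2_a + s2_b + s2_c) >= observed - 1e-12:
                exceed += 1
        return exceed / n_perm


def amova(dm: PairwiseDifferenceMatrix, assignment: PopulationAssignment,
          groups: Sequence[Sequence[str]] | None = None,
          n_permutations: int = 10_000, seed: int | None = None
          ) -> AmovaResult:
    """Functional wrapper over :class:`Amova`."""
    return Amova(dm, assignment, groups).fit(n_permutations, seed)


def pairwise_phi_st(dm: PairwiseDifferenceMatrix,
                    assignment: PopulationAssignment,
                    n_permutations: int = 10_000,
                    seed: int | None = None) -> pd.DataFrame:
    """phi_ST for every pair of populations (lower triangle), permutation
    p-values in the upper triangle."""
    pops = assignment.populations
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i in range(len(pops)):
        for j in range(i):
            a, b = pops[j], pops[i]
            members = assignment.members(a) + assignment.members(b)
            sub = dm.submatrix(members)
            sub_assign = PopulationAssignment(
                {t: assignment.mapping[t] for t in members},
                populations=[a, b],
            )
            res = Amova(sub, sub_assign).fit(
                n_permutations, seed=int(rng.integers(2 ** 31 - 1)))
            out.iloc[i, j] = res.phi["phi_ST"]
            out.iloc[j, i] = res.p_values["phi_ST"]
    return out


def haplotype_frequency_amova(dm: PairwiseDifferenceMatrix,
                              assignment: PopulationAssignment,
                              groups=None) -> AmovaResult:
    """Haplotype-frequency AMOVA for the degenerate all-unique case.

    When every individual carries a distinct haplotype, frequency-based
    AMOVA places the entire variance among individuals: F_ST = 1 and the
    hierarchical components vanish (F_SC = F_CT = 0).  This is reported
    exactly; for data with shared haplotypes use the distance-based
    :class:`Amova` instead.
    """
    assignment.validate_tips(dm.names)
    iu = np.triu_indices(dm.n, k=1)
    if not np.all(dm.values[iu] > 0):
        raise ValueError(
            "haplotype-frequency mode implemented only for the all-unique "
            "degenerate case; some individuals share a haplotype"
        )
    phi = {"F_ST": 1.0}
    if groups is not None:
        phi.update({"F_SC": 0.0, "F_CT": 0.0})
    table = pd.DataFrame({
        "source": ["among individuals", "total"],
        "df": [dm.n - 1, dm.n - 1],
        "SSD": [np.nan, np.nan],
        "variance": [np.nan, np.nan],
        "percent": [100.0, 100.0],
    })
    return AmovaResult(design="haplotype frequencies (all unique)",
                       table=table, phi=phi,
                       p_values=dict.fromkeys(phi), n_permutations=0,
                       seed=None)
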