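"""Alignments and pairwise nucleotide difference matrices.

Differences are counted with pairwise deletion: a site contributes to a
pair's count only when both sequences carry an unambiguous A/C/G/T there,
so gaps, Ns and IUPAC ambiguity codes never inflate a distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "PairwiseDifferenceMatrix",
    "pairwise_differences",
    "site_counts",
    "SiteCounts",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


class Alignment:
    """Equal-length named nucleotide sequences."""

    def __init__(self, names: Sequence[str], sequences: Sequence[str]):
        names = list(names)
        if len(names) != len(set(names)):
            raise ValueError("sequence names must be unique")
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("all sequences must have equal length")
        (self.length,) = lengths
        if self.length == 0:
            raise ValueError("zero-length alignment")
        self.names = names
        # 0..3 for A/C/G/T, 255 for anything else (gap, N, ambiguity)
        self.codes = np.vstack([
            _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            for s in sequences
        ])
        self._sequences = [s.upper() for s in sequences]

    def sequence(self, name: str) -> str:
        return self._sequences[self.names.index(name)]

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self._sequences):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")


class PairwiseDifferenceMatrix:
    """n x n integer counts of nucleotide differences among named samples."""

    def __init__(self, names: Sequence[str], values) -> None:
        names = list(names)
        values = np.asarray(values)
        n = len(names)
        if values.shape != (n, n):
            raise ValueError("matrix shape must match number of names")
        if np.any(values < 0):
            raise ValueError("difference counts must be non-negative")
        if np.any(np.diag(values) != 0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(values, values.T):
            raise ValueError("difference matrix must be symmetric")
        self.names = names
        self.values = values.astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.names)

    def get(self, a: str, b: str) -> int:
        return int(self.values[self.names.index(a), self.names.index(b)])

    def submatrix(self, members: Sequence[str]) -> "PairwiseDifferenceMatrix":
        idx = [self.names.index(m) for m in members]
        return PairwiseDifferenceMatrix(
            [self.names[i] for i in idx], self.values[np.ix_(idx, idx)]
        )

    def within_pair_values(self, members: Sequence[str]) -> np.ndarray:
        """Sorted multiset of differences among all pairs within ``members``."""
        idx = [self.names.index(m) for m in members]
        sub = self.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return np.sort(sub[iu])

    @classmethod
    def from_tsv(cls, path) -> "PairwiseDifferenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("difference matrix TSV must have matching "
                             "row and column sample names")
        return cls(list(df.columns), df.to_numpy(dtype=np.int64))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.names,
                     columns=self.names).to_csv(path, sep="\t")


def pairwise_differences(aln: Alignment) -> PairwiseDifferenceMatrix:
    """Count per-pair nucleotide differences with pairwise deletion."""
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    codes = aln.codes
    valid = codes != 255
    n = aln.n_sequences
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (codes[i] != codes[i + 1:]) & both
        out[i, i + 1:] = diff.sum(axis=1)
    out = out + out.T
    return PairwiseDifferenceMatrix(aln.names, out)


@dataclass(frozen=True)
class SiteCounts:
    variable: int
    informative: int


def site_counts(aln: Alignment) -> SiteCounts:
    """Variable and parsimony-informative site counts.

    Both are computed over unambiguous characters only.  A site is variable
    when >= 2 distinct A/C/G/T states occur; parsimony-informative when
    >= 2 states are each present in >= 2 sequences.
    """
    codes = aln.codes
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])  # 4 x L
    n_states = (counts >= 1).sum(axis=0)
    n_shared = (counts >= 2).sum(axis=0)
    return SiteCounts(
        variable=int((n_states >= 2).sum()),
        informative=int((n_shared >= 2).sum()),
    )
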