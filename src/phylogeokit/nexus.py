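"""NEXUS export of randomized label matrices in the a/g/c/t encoding.

Up to four populations can be encoded as the DNA states a, g, c, t, which
lets an external parsimony program (e.g. PAUP* with datatype=dna and
user-defined step matrices) cross-check the dispersal-length engine: each
NEXUS character is one randomized assignment of populations over the tips.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["encode_labels_nexus", "POP_STATE_CODES"]

POP_STATE_CODES = "agct"


def encode_labels_nexus(tip_names: Sequence[str], label_matrix,
                        populations: Sequence[str]) -> str:
    """Render an (R, n_tips) integer label matrix as a NEXUS data block.

    Population index i (into ``populations``) is written as the DNA state
    ``POP_STATE_CODES[i]``; taxa are rows, randomizations are characters.
    """
    label_matrix = np.asarray(label_matrix, dtype=np.int64)
    if label_matrix.ndim != 2 or label_matrix.shape[1] != len(tip_names):
        raise ValueError("label matrix must be (n_replicates, n_tips)")
    if len(populations) > len(POP_STATE_CODES):
        raise ValueError("a/g/c/t encoding supports at most 4 populations")
    if label_matrix.min() < 0 or label_matrix.max() >= len(populations):
        raise ValueError("label index out of range")
    R, n = label_matrix.shape
    name_w = max(len(t) for t in tip_names) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={n} NCHAR={R};",
        "    FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "    MATRIX",
    ]
    legend = "  ".join(f"{POP_STATE_CODES[i]}={p}"
                       for i, p in enumerate(populations))
    lines.insert(1, f"[ population encoding: {legend} ]")
    for j, tip in enumerate(tip_names):
        states = "".join(POP_STATE_CODES[s] for s in label_matrix[:, j])
        lines.append(f"    {tip:<{name_w}}{states}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)
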