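import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from phylogeokit import (CostMatrix, LabeledTree, ModelSpec,
                         PopulationAssignment, build_cost_matrix)


@pytest.fixture
def island4() -> CostMatrix:
    return build_cost_matrix(ModelSpec("island", list("rogb")))


@pytest.fixture
def six_tip_tree() -> LabeledTree:
    return LabeledTree.from_newick("(((x1,x2),x3),((y1,y2),y3));")


@pytest.fixture
def six_tip_labels() -> PopulationAssignment:
    return PopulationAssignment(
        {"x1": "X", "x2": "X", "x3": "X", "y1": "Y", "y2": "Y", "y3": "Y"}
    )


def random_symmetric_costs(k: int, rng: np.random.Generator) -> CostMatrix:
    m = rng.integers(1, 6, size=(k, k)).astype(float)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    names = [f"P{i}" for i in range(k)]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # triangle violations are fine here
        return CostMatrix(names, m)
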