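import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metacrit.io import ExpressionMatrix, GeneSetCollection, StageDesign

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def expr_from(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def two_stage_design():
    """10 samples split into a reference and a tumor stage."""
    mapping = {f"s{j}": ("Normal" if j < 5 else "Stage I") for j in range(10)}
    return StageDesign(mapping, ("Normal", "Stage I"), "Normal")


@pytest.fixture
def small_pathways():
    return GeneSetCollection({
        "P1": ("first", ["g0", "g1", "g2"]),
        "P2": ("second", ["g3", "g4", "g5"]),
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
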