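import numpy as np
import pandas as pd
import pytest

from nanovax.cleavage import SUBSITES, SpecificityMatrix, load_cathepsin_b_matrix
from nanovax.constructs import AMINO_ACIDS, study_constructs


@pytest.fixture(scope="session")
def study():
    """The four annotated study constructs p1-p4."""
    return study_constructs()


@pytest.fixture(scope="session")
def cathb_matrix():
    """Bundled synthetic cathepsin-B-like matrix fixture."""
    return load_cathepsin_b_matrix()


@pytest.fixture
def zero_matrix():
    df = pd.DataFrame(0.0, index=list(SUBSITES), columns=list(AMINO_ACIDS))
    return SpecificityMatrix(protease="null", scores=df)


def make_matrix_from_array(arr: np.ndarray, protease: str = "test") -> SpecificityMatrix:
    df = pd.DataFrame(arr, index=list(SUBSITES), columns=list(AMINO_ACIDS))
    return SpecificityMatrix(protease=protease, scores=df)


def brute_force_scores(sequence: str, matrix: SpecificityMatrix) -> dict[int, float]:
    """Independent window scorer: explicit double loop, no vectorization."""
    offsets = (-3, -2, -1, 0, 1, 2, 3, 4)
    out = {}
    L = len(sequence)
    for bond in range(4, L - 3):
        total = 0.0
        for subsite, off in zip(SUBSITES, offsets):
            total += matrix.score_of(subsite, sequence[bond + off - 1])
        out[bond] = total
    return out
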