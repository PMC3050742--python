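import numpy as np
import pytest
from hypothesis import settings

from moaclust import DescriptorSet, SimilarityMatrix

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def toy_sim() -> SimilarityMatrix:
    """Four compounds A–D with hand-set pairwise similarities.

    S(A,B)=0.9, S(A,C)=0.2, S(A,D)=0.3, S(B,C)=0.25, S(B,D)=0.35,
    S(C,D)=0.8 — small enough to enumerate every clustering rule by hand.
    """
    ids = ("A", "B", "C", "D")
    m = np.array(
        [
            [1.0, 0.9, 0.2, 0.3],
            [0.9, 1.0, 0.25, 0.35],
            [0.2, 0.25, 1.0, 0.8],
            [0.3, 0.35, 0.8, 1.0],
        ]
    )
    return SimilarityMatrix(ids=ids, values=m, set_id=DescriptorSet.ECFP4)


def random_similarity_matrix(rng: np.random.Generator, n: int) -> SimilarityMatrix:
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    ids = tuple(f"c{i}" for i in range(n))
    return SimilarityMatrix(ids=ids, values=m, set_id=DescriptorSet.ECFP4)
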