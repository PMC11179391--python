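import numpy as np
import pytest

from dpcollab.model import FeatureEncoding, GenerativeParams


@pytest.fixture
def tiny_params() -> GenerativeParams:
    """Two-component model over (3, 2)-level features with a rare outcome."""
    return GenerativeParams(
        np.array([0.6, 0.4]),
        ((np.array([0.7, 0.2, 0.1]), np.array([0.5, 0.5])),
         (np.array([0.1, 0.3, 0.6]), np.array([0.9, 0.1]))),
        np.array([-2.0, 0.5, -0.4, 0.6]),
    )


@pytest.fixture
def tiny_encoding() -> FeatureEncoding:
    return FeatureEncoding((3, 2))


def random_params(rng: np.random.Generator, R: int,
                  level_counts: tuple[int, ...]) -> GenerativeParams:
    theta = tuple(
        tuple(rng.dirichlet(np.ones(l)) for l in level_counts)
        for _ in range(R)
    )
    p = 1 + sum(l - 1 for l in level_counts)
    return GenerativeParams(rng.dirichlet(np.ones(R)), theta,
                            rng.normal(0, 1, p))
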