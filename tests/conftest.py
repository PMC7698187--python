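import numpy as np
import pytest

from efnn.eda_sof import SampleMatrix
from efnn.synthetic_data import MixtureComponent, MixtureSpec, gen_mixture_stream


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def two_class_random(rng):
    """Unstructured labelled 100 x 5 matrix for oracle-equivalence checks."""
    X = rng.normal(size=(100, 5))
    y = rng.integers(0, 2, size=100)
    y[:2] = [0, 1]  # both classes guaranteed
    return SampleMatrix(X, y)


def four_blob_spec(n_samples: int, seed: int = 1) -> MixtureSpec:
    """2 classes x 2 well-separated components in 2-D."""
    return MixtureSpec(
        n_features=2,
        classes=[
            [MixtureComponent([0, 0], [0.5, 0.5], 0.5),
             MixtureComponent([5, 0], [0.5, 0.5], 0.5)],
            [MixtureComponent([0, 5], [0.5, 0.5], 0.5),
             MixtureComponent([5, 5], [0.5, 0.5], 0.5)],
        ],
        class_priors=[0.5, 0.5],
        n_samples=n_samples,
        seed=seed,
    )


@pytest.fixture
def four_blob_stream():
    return gen_mixture_stream(four_blob_spec(2000, seed=1))
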