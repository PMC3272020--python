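import warnings

import numpy as np
import pytest

from dmmix import CountMatrix, DirichletComponent, FitConfig, MixtureModel, fit_dmm


@pytest.fixture(autouse=True)
def _quiet_user_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def toy_counts() -> CountMatrix:
    rng = np.random.default_rng(0)
    return CountMatrix(counts=rng.integers(0, 20, size=(5, 3)))


@pytest.fixture
def uniform_pair() -> DirichletComponent:
    return DirichletComponent.from_alpha([1.0, 1.0])


@pytest.fixture
def toy_mixture(uniform_pair) -> MixtureModel:
    return MixtureModel(
        components=[uniform_pair, DirichletComponent.from_alpha([10.0, 10.0])],
        weights=np.array([0.5, 0.5]),
    )


@pytest.fixture
def toy_fit(toy_counts) -> "tuple":
    cfg = FitConfig(seed=2)
    return fit_dmm(toy_counts, 2, cfg), cfg
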