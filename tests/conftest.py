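import numpy as np
import pytest
from hypothesis import settings

import matsec as ms
from matsec.automl import make_config_grid

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")

RIDGE_GRID_SPEC = {
    "selectors": [{"alpha": 0.05, "max_features": 50}],
    "classifiers": [{"family": "ridge-logistic", "penalty": lam} for lam in (0.1, 1.0, 10.0)],
}


@pytest.fixture(scope="session")
def ridge_grid():
    return make_config_grid(RIDGE_GRID_SPEC)


@pytest.fixture(scope="session")
def fixture_records():
    """Small labelled synthetic dataset shared by fast tests."""
    return ms.generate_records(ms.GeneratorSpec(n_secretory=60, n_cytoplasmic=60, seed=11))


@pytest.fixture(scope="session")
def decision_models(ridge_grid):
    """A trained (preprotein, mature) model pair for combined decisions.

    The preprotein component uses a short signal-peptide-focused window with
    the positional binary groups; the mature component the default window
    with all nine feature groups.
    """
    train = ms.generate_records(ms.GeneratorSpec(n_secretory=200, n_cytoplasmic=200, seed=5))
    pre = ms.train_view(
        train,
        "preprotein",
        groups=["bin_individual", "bin_relaxed", "bin_compact"],
        grid=ridge_grid,
        K=5,
        seed=2,
        bbc_B=0,
        W=30,
    )
    mat = ms.train_view(train, "mature", grid=ridge_grid, K=5, seed=2, bbc_B=0)
    return pre, mat


def linear_model(feature_names, coefficients, sds=None, intercept=0.0, threshold=0.5):
    """Hand-built ridge-logistic TrainedModel for formula-level tests."""
    n = len(feature_names)
    return ms.TrainedModel(
        view="mature",
        window_length=80,
        groups=["bin_individual"],
        selected_features=list(feature_names),
        means=[0.0] * n,
        sds=list(sds) if sds is not None else [1.0] * n,
        family="ridge-logistic",
        params={},
        threshold=threshold,
        coefficients=list(coefficients),
        intercept=intercept,
    )


@pytest.fixture
def make_linear_model():
    return linear_model


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test RNG (hash is stable across processes)."""
    import zlib

    return np.random.default_rng(zlib.crc32(name.encode()) % (2**31))
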