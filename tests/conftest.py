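import numpy as np
import pytest

import svrqsar as q


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_synthetic():
    """Low-dimensional dataset with clear signal (5 informative only)."""
    spec = q.SyntheticSpec(n=40, D=8, k=5, r=0, rho=0.0, n_constant=0,
                           noise_sd=0.2, effect="linear", seed=7)
    matrix, activities, truth = q.generate(spec)
    data = q.make_modeling_dataset(matrix, activities)
    return data, truth


@pytest.fixture(scope="session")
def benchmark_runs():
    """Full selection pipeline on the default benchmark, seeds 1..20.

    Session-scoped because each replicate runs thousands of SVR fits;
    several tests consume different slices of the same runs.
    """
    runs = []
    for seed in range(1, 21):
        matrix, activities, truth = q.generate(q.SyntheticSpec(seed=seed))
        data = q.make_modeling_dataset(matrix, activities)
        cv = q.CVScheme(mode="kfold", k=10, seed=seed)
        retained, trace = q.select_descriptors(data, svr=q.SVRConfig(), cv=cv)
        runs.append({"seed": seed, "truth": truth, "retained": retained,
                     "trace": trace, "data": data})
    return runs
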