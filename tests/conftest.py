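import dataclasses

import pytest

import bindprof as bp


def mst_spec(seed: int = 1, kd: float = 10e-9, **overrides) -> bp.SyntheticSpec:
    """MST study conditions with a configurable true KD."""
    spec = bp.preset("mst_ca", seed=seed)
    return dataclasses.replace(
        spec, shared=bp.SharedBindingParams(KD=kd), name="", **overrides
    )


@pytest.fixture(scope="session")
def mst_dataset():
    """One seeded noisy MST dataset at the default study conditions."""
    return bp.generate(mst_spec(seed=1))


@pytest.fixture(scope="session")
def noise_free_mst_dataset():
    return bp.generate(mst_spec(seed=1, sigma_abs=0.0, sigma_rel=0.0))


@pytest.fixture(scope="session")
def hill_dataset():
    return bp.generate(bp.preset("fph", seed=2))


@pytest.fixture(scope="session")
def quick_config():
    """Reduced start count for tests that exercise contracts, not accuracy."""
    return bp.FitConfig(n_starts=8)


@pytest.fixture(scope="session")
def mst_fit(mst_dataset, quick_config):
    return bp.multistart_fit(mst_dataset, "mst", quick_config)
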