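import numpy as np
import pytest

import trabl
from trabl.phantom import make_preset


@pytest.fixture(scope="session")
def preset_cache():
    """Generate each phantom preset at most once per test session."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = make_preset(name)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def pipeline_cache(preset_cache):
    """Run the default 100x100 pipeline at most once per preset."""
    cache = {}

    def get(name, **kwargs):
        key = (name, tuple(sorted(kwargs.items())))
        if key not in cache:
            deficient, reconstructed, config, truth = preset_cache(name)
            result, state = trabl.run_case_objects(deficient, reconstructed,
                                                   config, **kwargs)
            cache[key] = (result, state, truth)
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def sphere_points(rng, center, radius, n):
    """Uniform points on a sphere (helper shared by several tests)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v
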