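import numpy as np
import pytest

from entropath.toy_system import (ModelSurfaceSpec, generate_ensemble,
                                  saddle_geometry, saddle_normal_modes)


@pytest.fixture(scope="session")
def default_spec():
    return ModelSurfaceSpec()


@pytest.fixture(scope="session")
def default_modes(default_spec):
    coords, topo = saddle_geometry(default_spec)
    return saddle_normal_modes(default_spec, topo), topo


@pytest.fixture(scope="session")
def small_ensemble(default_spec):
    """A modest symmetric ensemble reused across I/O and profiling tests."""
    return generate_ensemble(default_spec, 120, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
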