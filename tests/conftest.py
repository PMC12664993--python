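import numpy as np
import pytest

from pentagate.synth import PentamerSpec, build_pentamer


@pytest.fixture(scope="session")
def default_spec():
    return PentamerSpec()


@pytest.fixture(scope="session")
def pentamer(default_spec):
    """Noise-free C5 pentamer at the calcium-bound study conditions."""
    return build_pentamer(default_spec)


@pytest.fixture(scope="session")
def scheme(default_spec):
    return default_spec.scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def rigid_motion(rng):
    """A random proper rotation + translation, for invariance checks."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-50, 50, 3)
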