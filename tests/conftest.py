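import numpy as np
import pytest

from dkimicro import TissueParams, study_protocol


@pytest.fixture(scope="session")
def scheme():
    """The emulated study protocol: 3 shells x 30 directions + 5 b=0."""
    return study_protocol()


@pytest.fixture(scope="session")
def reference_params():
    """The fixed reference tissue configuration used across the suite."""
    return TissueParams(f=0.7, Da=2.2, De_par=1.8, De_perp=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Haar-ish random rotation matrix from a QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
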