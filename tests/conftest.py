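import numpy as np
import pytest

from renulm.pipeline import SessionConfig
from renulm.synthetic import (
    HemodynamicsParams,
    PhantomConfig,
    RenderParams,
    build_renal_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """Default renal phantom (built once per test session)."""
    return build_renal_phantom(PhantomConfig())


@pytest.fixture
def hemo():
    return HemodynamicsParams()


@pytest.fixture
def short_config():
    """A 20-s desk-scale session config for fast end-to-end tests."""
    return SessionConfig(scan_duration=20.0, t_inj=6.0)


def make_blob_frame(shape, r0, c0, sigma_px, amplitude=100.0):
    """Render one Gaussian blob with sub-pixel center (r0, c0) in pixel units
    of pixel-center coordinates (blob at pixel i means r0 = i)."""
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_px ** 2))


# deterministic hypothesis runs
from hypothesis import settings as _hyp_settings  # noqa: E402

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
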