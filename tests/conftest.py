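import numpy as np
import pytest

from earfield.forward import compute_leadfield
from earfield.head import make_default_head


@pytest.fixture(scope="session")
def default_head():
    """The default study head (seed 42): 2562-vertex folded cortex, 5 mm
    volume grid, 128-channel cap, bilateral 10-electrode ear grids,
    50-patch left-lateral parcellation."""
    return make_default_head(42)


@pytest.fixture(scope="session")
def leadfields(default_head):
    """Surface-normal, average-referenced lead fields for the cap and the
    bilateral ear montage on the default head."""
    head = default_head
    lf_cap = compute_leadfield(head.cap, head.cortex, head.shell)
    lf_ear = compute_leadfield(head.ear_montage, head.cortex, head.shell)
    return lf_cap, lf_ear


@pytest.fixture(scope="session")
def small_head():
    """A reduced head for fast I/O and CLI tests: coarse cortex, sparse cap,
    few patches."""
    return make_default_head(
        3,
        cortex_subdivision_level=2,
        cap_n_electrodes=32,
        n_patches=8,
        grid_spacing=0.015,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
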