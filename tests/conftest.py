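import numpy as np
import pytest

import focitrack as ft


@pytest.fixture(scope="session")
def xsec():
    return ft.default_xsec()


@pytest.fixture(scope="session")
def track_10kev(xsec):
    """One full-cascade 10 keV track reused across scoring tests."""
    return ft.simulate_track(10e3, xsec, seed=12345)


@pytest.fixture(scope="session")
def tracks_1kev(xsec):
    """Twenty 1 keV tracks for pooled-statistics tests."""
    return [ft.simulate_track(1e3, xsec, seed=s) for s in range(20)]


@pytest.fixture
def separated_foci_fixture():
    """Noise-free nucleus with 25 well-separated foci at sub-pixel positions."""
    rng = np.random.default_rng(42)
    xs = np.linspace(3.5, 12.5, 5)
    ys = np.linspace(3.2, 8.8, 5)
    centers = [
        (x + rng.uniform(0, 0.1), y + rng.uniform(0, 0.1)) for x in xs for y in ys
    ]
    areas = list(np.linspace(0.2, 0.6, 25))
    image, truth = ft.synthesize_nucleus_image(
        25, noise_sd=0.0, seed=0, centers_um=centers, areas_um2=areas
    )
    return image, truth
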