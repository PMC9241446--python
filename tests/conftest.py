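import numpy as np
import pytest

from bscbmark import dti
from bscbmark.synthetic import (
    DCEPhantomSpec,
    VesselPhantomSpec,
    generate_dce_series,
    generate_dwi_phantom,
    generate_vessel_image,
    naive_cord_spec,
)


@pytest.fixture(scope="session")
def naive_phantom():
    """Noiseless healthy-cord phantom with the 55% white-matter annulus."""
    return generate_dwi_phantom(naive_cord_spec(seed=0))


@pytest.fixture(scope="session")
def naive_maps(naive_phantom):
    tensors = dti.fit_tensor(naive_phantom.stack)
    return dti.compute_scalar_maps(tensors, naive_phantom.cord_mask, naive_phantom.wm_mask)


@pytest.fixture(scope="session")
def dce_phantom_clean():
    """Noiseless 11-slice enhancement phantom with distinct true slopes."""
    slopes = tuple(0.01 * k for k in range(1, 12))
    return generate_dce_series(DCEPhantomSpec(slice_slopes=slopes, noise_sigma=0.0))


@pytest.fixture(scope="session")
def annulus_phantom():
    """Single clean vessel annulus r_in=12, r_out=20 with marker and halo."""
    spec = VesselPhantomSpec(
        vessels=(((128.0, 128.0), 12.0, 20.0),),
        marker_coverage=0.5,
        collagen_halo_width=5.0,
        noise_sigma=0.0,
    )
    return generate_vessel_image(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
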