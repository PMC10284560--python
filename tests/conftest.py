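import numpy as np
import pytest

from aztomo import phantom, tomio


@pytest.fixture(scope="session")
def noiseless_phantom():
    """The reference 128^3 validation phantom, generated once per session."""
    spec = phantom.validation_phantom()
    density, labels, gt = phantom.generate_phantom(spec)
    return spec, density, labels, gt


@pytest.fixture()
def small_spec():
    """A fast 64^3 phantom with three vesicles at distances 4/8/16 nm."""
    spec = phantom.PhantomSpec(volume_shape=(64, 64, 64), voxel_size_nm=1.4,
                               membrane_top_nm=13.3, az_extent_nm=70.0,
                               noise_sigma=0.0)
    for i, (d, yx) in enumerate([(4.0, (28.0, 26.0)), (8.0, (28.0, 62.0)),
                                 (16.0, (62.0, 44.0))]):
        spec.vesicles.append(phantom.VesicleSpec(10 + i, yx[0], yx[1], 13.0, d))
    return spec


def random_toy_grid(rng, shape=(10, 10, 10)):
    """Random density + labels for oracle-equivalence stress tests.

    AZ membrane plane at z=0, two 2-voxel-cube 'vesicles' at random interior
    positions, random uniform density; the analysis region is everything else.
    """
    density = rng.uniform(0.0, 1.0, size=shape).astype(np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    labels[0, :, :] = tomio.AZ_MEMBRANE
    for vid in (10, 11):
        z = rng.integers(2, shape[0] - 2)
        y = rng.integers(0, shape[1] - 2)
        x = rng.integers(0, shape[2] - 2)
        labels[z:z + 2, y:y + 2, x:x + 2] = vid
    region = labels == 0
    return density, labels, region
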