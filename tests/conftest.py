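import numpy as np
import pytest

from neckangle import PhantomSpec, build_phantom

# validation-study voxel size used throughout the tests: isotropic 0.8 mm
STUDY_SPACING = (0.8, 0.8, 0.8)


@pytest.fixture(scope="session")
def phantom_zero():
    """Noiseless phantom at zero displacement."""
    return build_phantom(PhantomSpec(set_angle=0.0, voxel_spacing=STUDY_SPACING,
                                     noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def phantom_p20():
    """Noiseless phantom at +20 degrees anteversion."""
    return build_phantom(PhantomSpec(set_angle=20.0, voxel_spacing=STUDY_SPACING,
                                     noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def phantom_p10_noisy():
    """Phantom at +10 degrees with study-level image noise."""
    return build_phantom(PhantomSpec(set_angle=10.0, voxel_spacing=STUDY_SPACING,
                                     noise_sd=25.0, seed=11))


def rigid_motion_2d(rng):
    """Random rotation + translation in the plane."""
    ang = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    t = rng.uniform(-50, 50, 2)
    return R, t
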