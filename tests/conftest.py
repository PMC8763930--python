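import numpy as np
import pytest

import thyropet as tp


@pytest.fixture(scope="session")
def noiseless_sphere_phantom():
    """14 mL spherical lesion, no noise, no shape perturbation."""
    spec = tp.PhantomSpec(
        lesion_volume_ml=14.0, shape_irregularity=0.0, noise_sd=0.0, seed=1
    )
    return tp.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = tp.PhantomSpec(
        lesion_volume_ml=8.0,
        shape_irregularity=0.4,
        texture_coarseness=0.6,
        noise_sd=0.1,
        seed=7,
    )
    return tp.generate_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort():
    return tp.generate_cohort(tp.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def digital_sphere_mask():
    """Radius-10-voxel digital sphere at unit spacing."""
    g = np.indices((45, 45, 45))
    d = np.sqrt(((g - 22) ** 2).sum(axis=0))
    return tp.LesionMask(d <= 10, (1.0, 1.0, 1.0))
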