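import numpy as np
import pytest

import strokesem as sk
import strokesem.labels as L


@pytest.fixture(scope="session")
def clean_phantom_spec() -> sk.PhantomSpec:
    """Noiseless well-separated phantom with one WML and one ischemic lesion."""
    return sk.PhantomSpec(
        grid_shape=(40, 40, 32),
        voxel_size=(2.0, 2.0, 2.0),
        lesions=(
            sk.Lesion("wml", (30, 20, 16), 6.0),
            sk.Lesion("ischemic", (20, 10, 16), 5.0),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_phantom_spec) -> sk.Phantom:
    return sk.make_phantom(clean_phantom_spec)


@pytest.fixture(scope="session")
def clean_maps(clean_phantom):
    tensor = sk.fit_tensor(clean_phantom.dwi_series, clean_phantom.brain_mask)
    return sk.diffusivity_maps(tensor)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / max(a.sum() + b.sum(), 1)
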