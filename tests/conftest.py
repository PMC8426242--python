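import numpy as np
import pytest

from petmtv.io import SUVVolume
from petmtv.phantom import Compartment, LesionSpec, PhantomConfig, generate_phantom

PAPER_SPACING = (3.18, 3.18, 5.0)


def make_volume(data, spacing=PAPER_SPACING, patient_id="test") -> SUVVolume:
    return SUVVolume(data=np.asarray(data, dtype=float), spacing=spacing,
                     patient_id=patient_id)


@pytest.fixture
def quiet_config() -> PhantomConfig:
    """Noise-free phantom with one 2.0-ml SUV-8 liver lesion."""
    cfg = PhantomConfig(
        background_noise_sd=0.0,
        blood_pool=Compartment("ellipsoid", (0.5, 0.5, 0.62), (12.0, 12.0, 45.0),
                               1.8, 0.0),
        liver=Compartment("box", (0.33, 0.5, 0.375), (45.0, 55.0, 32.0), 2.2, 0.0),
        lesions=[LesionSpec("L1", "liver", 2.0, 8.0)],
        seed=7,
    )
    return cfg


@pytest.fixture
def quiet_phantom(quiet_config):
    return generate_phantom(quiet_config)
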