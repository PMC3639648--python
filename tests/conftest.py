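import numpy as np
import pytest

from vesselcut.io_fixtures import (
    DiskDistractor,
    PhantomSpec,
    VesselPath,
    generate_phantom,
)


@pytest.fixture(scope="session")
def ridge_phantom():
    """One clean horizontal vessel (half-width 4) through a 64x64 field —
    the minimal tube every stage should respond to."""
    spec = PhantomSpec(
        (64, 64),
        vessel_paths=(VesselPath(((32.0, 6.0), (32.0, 57.0)), 4.0, 0.3),),
        noise_sigma=0.0,
        rng_seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_two_width_phantom():
    """Two vessels of half-widths 2 and 6 with mild noise, for scale and
    denoising checks."""
    spec = PhantomSpec(
        (96, 96),
        vessel_paths=(
            VesselPath(((24.0, 6.0), (26.0, 89.0)), 2.0, 0.25),
            VesselPath(((68.0, 6.0), (66.0, 89.0)), 6.0, 0.25),
        ),
        noise_sigma=0.03,
        rng_seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def vessel_disk_phantom():
    """A vessel and an equal-contrast bright disk distractor."""
    spec = PhantomSpec(
        (128, 128),
        vessel_paths=(VesselPath(((34.0, 8.0), (38.0, 119.0)), 5.0, 0.25),),
        disk_distractor=DiskDistractor((86.0, 64.0), 16.0, -0.25),
        noise_sigma=0.02,
        rng_seed=3,
    )
    return generate_phantom(spec)
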