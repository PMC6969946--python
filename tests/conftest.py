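import numpy as np
import pytest

from aperture3d.geometry import StimulusCondition, ViewingGeometry


@pytest.fixture(scope="session")
def geom():
    return ViewingGeometry()


@pytest.fixture(scope="session")
def exp1_sweep():
    """Exp-1-style sweep at +IOVD: tilt 0, orientation disparity -6..6."""
    return [
        StimulusCondition(tilt_deg=0.0, orientation_disparity_deg=d, iovd_sign=1)
        for d in (-6, -4, -2, 0, 2, 4, 6)
    ]


def random_condition(rng: np.random.Generator) -> StimulusCondition:
    """A random but physically valid line-motion condition."""
    return StimulusCondition(
        tilt_deg=float(rng.uniform(0.0, 180.0)),
        orientation_disparity_deg=float(rng.uniform(-10.0, 10.0)),
        iovd_sign=int(rng.choice([-1, 1])),
        base_speed_deg=float(rng.uniform(1.0, 5.0)),
        iovd_magnitude_deg=float(rng.uniform(0.1, 1.0)),
        experiment=1,
    )
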