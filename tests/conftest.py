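import numpy as np
import pytest

from rosetteroll.synthetic import (
    DurationSpec,
    RosetteParams,
    sample_motor_telegraph,
    simulate_rolling_rosette,
)


@pytest.fixture(scope="session")
def rosette_ensemble():
    """Nine 120-s rolling-rosette tracks with exponential 1-s motor switching."""
    tracks = []
    params = RosetteParams(radius=4.0, omega=1.0, q_true=0.9, speed=3.6)
    for i in range(9):
        tel = sample_motor_telegraph(DurationSpec("exponential", mean=1.0), 120.0, 100 + i)
        out = simulate_rolling_rosette(
            params, tel, None, 120.0, 0.05, 200 + i, unit_id=f"rosette-{i}"
        )
        tracks.append(out)
    return tracks


@pytest.fixture
def rng():
    return np.random.default_rng(0)
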