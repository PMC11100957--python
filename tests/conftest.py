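import numpy as np
import pytest

from gaitcue import (
    G,
    GaitScenario,
    ImuStream,
    detect_phases,
    estimate_orientation,
    generate,
)
from gaitcue.simulate import Segment


def make_static_stream(duration_s: float = 5.0, tilt_deg: float = 0.0,
                       noise_sd: float = 0.0, seed: int = 0) -> ImuStream:
    """A motionless foot at a fixed toe-up tilt."""
    n = int(duration_s * 200)
    t = np.arange(n) / 200.0
    th = np.deg2rad(tilt_deg)
    acc = np.tile([G * np.sin(th), 0.0, G * np.cos(th)], (n, 1))
    gyr = np.zeros((n, 3))
    if noise_sd:
        rng = np.random.default_rng(seed)
        acc = acc + rng.normal(0, noise_sd, (n, 3))
        gyr = gyr + rng.normal(0, 10 * noise_sd, (n, 3))
    return ImuStream(t=t, acc=acc, gyr=gyr).validate()


@pytest.fixture(scope="session")
def walk_session():
    """Ten normal strides at 1 Hz cadence, default noise."""
    scn = GaitScenario(segments=[Segment("rest", duration=2.0),
                                 Segment("normal_walk", n_strides=10),
                                 Segment("rest", duration=1.0)], seed=1)
    stream, truth = generate(scn)
    orient = estimate_orientation(stream)
    seq = detect_phases(stream, orient)
    return stream, truth, orient, seq


@pytest.fixture(scope="session")
def mixed_session():
    """Normal gait interleaved with all detectable FoG subtypes and a turn."""
    scn = GaitScenario(segments=[Segment("rest", duration=2.0),
                                 Segment("normal_walk", n_strides=8),
                                 Segment("shuffling", n_strides=5),
                                 Segment("trembling", duration=4.0),
                                 Segment("festination", n_strides=6),
                                 Segment("turn", params={"angle_deg": 180.0}),
                                 Segment("normal_walk", n_strides=6),
                                 Segment("rest", duration=1.0)], seed=7)
    stream, truth = generate(scn)
    orient = estimate_orientation(stream)
    seq = detect_phases(stream, orient)
    return stream, truth, orient, seq
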