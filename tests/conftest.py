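import numpy as np
import pytest

from casakit import DetectionParams, FieldFrame, ParticleSet
from casakit.imaging import Particle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def frame_from(array, scale=1.0, frame_index=0):
    return FieldFrame(np.asarray(array), scale, frame_index)


def particle_set(points, width, height, scale=1.0, frame_index=0):
    """Build a ParticleSet from raw (x, y) centroids for geometry tests."""
    particles = [Particle(float(x), float(y), scale * scale, 1) for x, y in points]
    return ParticleSet(particles, frame_index, width, height, scale)


@pytest.fixture
def detection_defaults():
    return DetectionParams(min_area_um2=10.0, max_area_um2=80.0)
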