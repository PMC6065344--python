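import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microwear.image_io import MarkRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_mark(mark_id, length, width, angle_deg=0.0, center=(100.0, 100.0),
              manual_label=None):
    """Build a mark with the given length/width axes about a centre point."""
    th = np.deg2rad(angle_deg)
    u = np.array([np.cos(th), np.sin(th)])
    n = np.array([-np.sin(th), np.cos(th)])
    c = np.asarray(center, dtype=float)
    p1, p2 = c - u * length / 2, c + u * length / 2
    p3, p4 = c - n * width / 2, c + n * width / 2
    return MarkRecord(mark_id, tuple(p1), tuple(p2), tuple(p3), tuple(p4),
                      manual_label=manual_label)


def segment_mark(mark_id, a, b, width=1.0):
    """Mark whose length axis is exactly the segment a–b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    v = b - a
    n = np.array([-v[1], v[0]]) / np.hypot(*v)
    c = (a + b) / 2
    return MarkRecord(mark_id, tuple(a), tuple(b),
                      tuple(c - n * width / 2), tuple(c + n * width / 2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
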