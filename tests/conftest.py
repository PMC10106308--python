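import numpy as np
import pytest

from annulokin.geometry import AnnulusFrame


def ellipse_ring(a=16.0, b=11.2, h=0.0, theta0=0.0, n=8):
    """n points on the (possibly saddle-shaped) ellipse ring.

    x = a cos(t), y = b sin(t), z = -h cos(2t): horns (high points) on the
    minor (septolateral) axis, commissures low.
    """
    th = theta0 + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(th), b * np.sin(th), -h * np.cos(2.0 * th)])


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230416)


@pytest.fixture
def ellipse_frame():
    return AnnulusFrame(points=ellipse_ring())


@pytest.fixture
def saddle_frame():
    return AnnulusFrame(points=ellipse_ring(h=2.0))


@pytest.fixture
def circle_frame():
    return AnnulusFrame(points=ellipse_ring(a=10.0, b=10.0))
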