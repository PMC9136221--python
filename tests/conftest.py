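import numpy as np
import pytest

import fasciclecontour as fc


def polygon(fn, n=360):
    theta = 2.0 * np.pi * np.arange(n) / n
    x, y = fn(theta)
    return np.column_stack([x, y])


@pytest.fixture(scope="session")
def circle360():
    """360-point circle of radius 10 centered at the origin."""
    return polygon(lambda t: (10 * np.cos(t), 10 * np.sin(t)))


@pytest.fixture(scope="session")
def ellipse360():
    """360-point axis-aligned ellipse with semi-axes (20, 10)."""
    return polygon(lambda t: (20 * np.cos(t), 10 * np.sin(t)))


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic analytic shapes (circle, ellipse, rounded square, star)."""
    return fc.make_fixtures()


@pytest.fixture(scope="session")
def disk_mask():
    """61x61 mask with a filled disk of radius 20 centered at (30, 30)."""
    yy, xx = np.mgrid[0:61, 0:61]
    return (((xx - 30) ** 2 + (yy - 30) ** 2) <= 20**2).astype(np.uint8)


# printed per-order metric rows of the worked order-selection example
TABLE1_DICE = [93.29, 94.20, 94.73, 95.17, 95.55, 95.95, 96.22]
TABLE1_H = [11.70, 7.81, 7.07, 5.83, 5.83, 5.10, 5.38]
TABLE1_HE = [1.07, 0.93, 0.84, 0.77, 0.71, 0.64, 0.61]
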