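import numpy as np
import pytest

from spectremri import (
    ColorVolume,
    GradientSpec,
    PhantomSpec,
    Streamline,
    StreamlineBundle,
    TrackingParams,
    make_tensor_phantom,
)


@pytest.fixture
def shipped_gradient() -> GradientSpec:
    """The shipped fronto-occipital three-Gaussian gradient."""
    return GradientSpec()


@pytest.fixture
def straight_phantom():
    spec = PhantomSpec()
    return spec, make_tensor_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20210227)


def make_bundle(point_lists, seed=None, params=None) -> StreamlineBundle:
    """Assemble a bundle from raw point lists (test helper)."""
    seed = np.zeros(3) if seed is None else np.asarray(seed, float)
    sls = [Streamline(np.asarray(p, float), seed) for p in point_lists]
    return StreamlineBundle(seed, sls, params or TrackingParams())


def unit_grid_color(data) -> ColorVolume:
    """Color volume on a unit-spacing grid at the origin."""
    return ColorVolume(np.asarray(data, float), np.eye(4), "subject")


def trilinear_oracle(data, point):
    """Independent scalar trilinear interpolation on a unit grid.

    Hand-rolled corner-weight formula; out-of-bounds corners contribute 0.
    """
    data = np.asarray(data, float)
    x, y, z = point
    out = 0.0
    i0, j0, k0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                i, j, k = i0 + di, j0 + dj, k0 + dk
                w = (
                    (1 - abs(x - i))
                    * (1 - abs(y - j))
                    * (1 - abs(z - k))
                )
                if w <= 0:
                    continue
                if 0 <= i < data.shape[0] and 0 <= j < data.shape[1] and 0 <= k < data.shape[2]:
                    out += w * data[i, j, k]
    return out
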