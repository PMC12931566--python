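import imageio.v3 as iio
import numpy as np
import pytest

from polychromia import ROIMask, RGBImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def write_png(tmp_path):
    """Write an array as PNG into the test's tmp dir; return its path."""

    def _write(name, arr):
        path = tmp_path / name
        iio.imwrite(path, np.asarray(arr))
        return path

    return _write


@pytest.fixture
def constant_image():
    """2x2 image with every pixel (10, 20, 30)."""

    def make(shape=(2, 2), rgb=(10, 20, 30)):
        return RGBImage(
            red=np.full(shape, rgb[0], dtype=np.uint8),
            green=np.full(shape, rgb[1], dtype=np.uint8),
            blue=np.full(shape, rgb[2], dtype=np.uint8),
        )

    return make


@pytest.fixture
def full_mask():
    def make(shape, label="lesional"):
        return ROIMask(selected=np.ones(shape, dtype=bool), label=label)

    return make


def random_image(rng, shape=(8, 8)):
    return RGBImage(
        red=rng.integers(0, 256, shape, dtype=np.uint8),
        green=rng.integers(0, 256, shape, dtype=np.uint8),
        blue=rng.integers(0, 256, shape, dtype=np.uint8),
    )
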