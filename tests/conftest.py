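import numpy as np
import pytest

from somaseg import FixtureConfig, make_toy_stack
from somaseg.io_formats import Contour, SomaAnnotation


@pytest.fixture(scope="session")
def toy_corpus():
    """One deterministic 64x64 toy stack with full and partial annotations."""
    config = FixtureConfig(seed=7)
    return make_toy_stack(config)


@pytest.fixture()
def square_annotation():
    def _make(x0, y0, side, region_id="sq"):
        return SomaAnnotation(
            contour=Contour(
                np.array(
                    [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side],
                     [x0, y0 + side]],
                    dtype=float,
                )
            ),
            region_id=region_id,
        )

    return _make


def mask_from_pixels(shape, pixels):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m
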