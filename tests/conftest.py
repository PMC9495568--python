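import numpy as np
import pytest

from probead import synthetic as syn


@pytest.fixture
def paper_timepoints():
    return np.asarray(syn.DEFAULT_TIMEPOINTS, dtype=float)


@pytest.fixture
def rasterized_disc():
    """Binary disc of radius 50 px with a margin, plus its radius."""

    def make(radius=50, margin=5):
        n = 2 * radius + 2 * margin + 1
        yy, xx = np.mgrid[:n, :n]
        c = n // 2
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius * radius

    return make


@pytest.fixture
def sierpinski_carpet():
    def make(depth=6):
        m = np.ones((1, 1), dtype=bool)
        for _ in range(depth):
            z = np.zeros_like(m)
            m = np.block([[m, m, m], [m, z, m], [m, m, m]])
        return m

    return make
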