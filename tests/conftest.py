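import numpy as np
import pytest

import nodereg as nr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_flow():
    """A nontrivial but smooth 2-D flow map (float64)."""
    gen = np.random.default_rng(7)
    net = nr.VelocityNetwork.create(2, (40, 40, 40), gen)
    W, b = net.params[-1]
    net.params[-1] = ((0.15 * gen.standard_normal(W.shape)).astype(W.dtype),
                      (0.1 * gen.standard_normal(b.shape)).astype(b.dtype))
    return nr.FlowMap(net.astype(np.float64))


@pytest.fixture(scope="session")
def disc_field():
    """Binary disc of radius 0.5 on [-1, 1]^2, 101x101 lattice."""
    n = 101
    ax = np.linspace(-1, 1, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    raster = (X ** 2 + Y ** 2 <= 0.25).astype(float)
    return nr.build_field(raster, origin=(-1, -1),
                          spacing=(ax[1] - ax[0],) * 2,
                          binarize_threshold=0.5)
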