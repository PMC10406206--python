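import numpy as np
import pytest

from ngfreg import DisplacementField, PathologyMask, ScalarVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def smooth_pair(rng):
    """A small pair of smooth random volumes on an anisotropic grid."""
    from scipy.ndimage import gaussian_filter

    n = 12
    spacing = np.array([1.0, 1.1, 0.9])
    r = ScalarVolume(gaussian_filter(rng.standard_normal((n, n, n)), 1.5), spacing)
    t = ScalarVolume(gaussian_filter(rng.standard_normal((n, n, n)), 1.5), spacing)
    return r, t


@pytest.fixture
def small_field(rng, smooth_pair):
    r, _ = smooth_pair
    u = rng.standard_normal(r.shape + (3,)) * 0.3
    return DisplacementField(u, r.spacing)


@pytest.fixture
def random_mask(rng, smooth_pair):
    r, _ = smooth_pair
    return PathologyMask((rng.random(r.shape) < 0.2).astype(np.uint8), r.spacing)


def finite_difference_gradient(fun, x, indices, step=1e-4):
    """Central finite differences of ``fun`` (value-only) at flat ``indices``."""
    out = []
    for i in indices:
        xp = x.ravel().copy()
        xm = x.ravel().copy()
        xp[i] += step
        xm[i] -= step
        out.append((fun(xp.reshape(x.shape)) - fun(xm.reshape(x.shape))) / (2 * step))
    return np.asarray(out)


def max_relative_gradient_error(fun_with_grad, x, rng, n_samples=50, step=1e-4):
    """Compare an analytic gradient against central finite differences."""
    _, g = fun_with_grad(x)
    g = np.asarray(g)
    idx = rng.choice(x.size, size=min(n_samples, x.size), replace=False)
    fd = finite_difference_gradient(lambda y: fun_with_grad(y)[0], x, idx, step)
    scale = max(np.abs(g).max(), 1e-12)
    return float(np.max(np.abs(fd - g.ravel()[idx]) / np.maximum(np.abs(fd), scale)))
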