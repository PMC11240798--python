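import numpy as np
import pytest

from surrocor.geometry import ContourSlice


def circle_contour(z=0.0, r=10.0, center=(0.0, 0.0), n=360):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    v = np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    return ContourSlice(z=z, vertices=v)


def random_star_polygon(rng, n_vertices=None, r_mean=100.0):
    """A random polygon star-shaped about the origin: jittered radii on a
    strictly increasing angle grid."""
    n = n_vertices or rng.integers(20, 200)
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    # enforce separation so edges are well conditioned
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False) + rng.uniform(
        0.0, 2 * np.pi / n / 2, size=n
    )
    radii = r_mean * rng.uniform(0.5, 1.5, size=n)
    v = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return ContourSlice(z=0.0, vertices=v)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom_config():
    """A 5-slice lag-free noise-free phantom with a uniform 5 mm amplitude."""
    from surrocor.phantom import PhantomConfig, constant_field

    return PhantomConfig(
        slice_zs=np.arange(0.0, 10.0, 2.0),
        amplitude_field=constant_field(5.0),
    )
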