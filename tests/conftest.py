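import numpy as np
import pytest

from pinreg3d import make_fixture_pair, reference_from_swatch


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pair7():
    """One shared synthetic fixture pair (seed 7, 30° displacement)."""
    return make_fixture_pair(seed=7, transform_magnitude=30.0)


@pytest.fixture(scope="session")
def pin_ref7(pair7):
    return reference_from_swatch(pair7.pin_swatch)


@pytest.fixture()
def random_cloud():
    def make(n=50, scale=20.0, seed=0, colored=True):
        from pinreg3d import ColoredCloud

        g = np.random.default_rng(seed)
        colors = g.random((n, 3)) if colored else None
        return ColoredCloud(g.normal(scale=scale, size=(n, 3)), colors)

    return make


def random_rigid_transform(g):
    from pinreg3d import RigidTransform

    axis = g.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = g.uniform(0, 180)
    T = RigidTransform.about_axis(axis, angle)
    return RigidTransform.from_rotation_translation(
        T.rotation, g.uniform(-50, 50, size=3))
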