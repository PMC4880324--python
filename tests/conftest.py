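import numpy as np
import pytest
import trimesh

import ffdedit as fe


@pytest.fixture(scope="session")
def unit_sphere() -> trimesh.Trimesh:
    """Unit icosphere at the origin, subdivision 3 (642 vertices)."""
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


@pytest.fixture(scope="session")
def sphere_10mm() -> trimesh.Trimesh:
    """10 mm sphere centered at (16, 16, 16) — fits a 32^3 / 1 mm volume."""
    s = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return trimesh.Trimesh(
        vertices=np.asarray(s.vertices) + 16.0, faces=s.faces, process=False
    )


@pytest.fixture(scope="session")
def geom32() -> fe.ImageGeometry:
    return fe.ImageGeometry(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def unit_cube() -> trimesh.Trimesh:
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0)).apply_translation(
        (0.5, 0.5, 0.5)
    )


@pytest.fixture(scope="session")
def scale_fixture() -> fe.Fixture:
    """The canonical degraded case: 20 mm sphere inflated by 10%."""
    return fe.make_fixture(fe.FixtureSpec())
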