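import numpy as np
import pytest

from rbc3d.descriptor import DescriptorConfig
from rbc3d.shapes import ShapeSpec, default_specs, make_canonical_mesh


@pytest.fixture(scope="session")
def canonical_meshes():
    """One canonical mesh per generatable class (session cache)."""
    return {spec.shape_class: make_canonical_mesh(spec) for spec in default_specs()}


@pytest.fixture(scope="session")
def disc_mesh(canonical_meshes):
    return canonical_meshes["discocyte"]


@pytest.fixture(scope="session")
def sphere_mesh():
    return make_canonical_mesh(ShapeSpec("spherocyte", diameter_um=6.0))


@pytest.fixture(scope="session")
def descriptor_config():
    return DescriptorConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
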