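import numpy as np
import pytest

import mammomc as mm
from mammomc.geometry import GeometryConfig


@pytest.fixture(scope="session")
def library():
    return mm.default_library()


@pytest.fixture(scope="session")
def materials():
    return mm.builtin_materials()


@pytest.fixture(scope="session")
def default_assembly():
    return mm.build_assembly()


@pytest.fixture(scope="session")
def slab_assembly():
    """Skinless box-mode three-layer stack for closed-form comparisons."""
    cfg = GeometryConfig(footprint="box", include_skin=False,
                         include_plates=False, include_body=False)
    return mm.build_assembly(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
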