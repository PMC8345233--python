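import numpy as np
import pytest

import vertebeam as vb


@pytest.fixture(scope="session")
def geometry():
    """Reduced 48-element linear array (0.3 mm pitch, 4 MHz)."""
    return vb.default_linear_geometry(48)


@pytest.fixture(scope="session")
def point_source_data(geometry):
    spec = vb.SceneSpec(kind="point_source", positions=[[1.0, 25.0]],
                        noise_level=0.0, seed=1)
    return vb.simulate_point_source(spec, geometry)


@pytest.fixture(scope="session")
def point_grid(point_source_data):
    import vertebeam.pipeline as P
    return P.default_grid(point_source_data, x_span=(-5, 5), z_span=(20, 30))


@pytest.fixture(scope="session")
def focused_point(point_source_data, point_grid):
    import vertebeam.focusing as F
    return F.focus_frame(point_source_data, point_grid)
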