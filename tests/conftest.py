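import numpy as np
import pytest

from fracmap.synthetic import PhantomSpec, make_template


@pytest.fixture(scope="session")
def small_spec():
    """Shortened phantom at coarser spacing: full distal geometry, fast grids."""
    return PhantomSpec(total_length=180.0, condylar_width=82.0,
                       shaft_radius=16.0, voxel_spacing=1.5, notch_depth=10.0)


@pytest.fixture(scope="session")
def small_template(small_spec):
    template, phantom = make_template(small_spec)
    return template, phantom
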