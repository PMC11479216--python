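import numpy as np
import pytest

from agrosuit.grid import GridLayer
from agrosuit.synthetic_data import LandscapeConfig, generate_landscape, generate_worked_matrices


@pytest.fixture(scope="session")
def hierarchy():
    return generate_worked_matrices()


@pytest.fixture(scope="session")
def landscape():
    """Default-condition synthetic landscape, small grid for speed."""
    return generate_landscape(LandscapeConfig(seed=42))


def make_layer(values, pixel_size=10.0, nodata=np.nan, units=""):
    vals = np.asarray(values, dtype=float)
    nr = vals.shape[0]
    return GridLayer(values=vals, pixel_size=pixel_size, origin=(0.0, nr * pixel_size),
                     nodata=nodata, units=units)
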