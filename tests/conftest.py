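import numpy as np
import pytest
from hypothesis import settings

from foragescape import GridRaster, GridTransform

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

CELL = 30.0


def transform(nrow: int = 10, x0: float = 0.0, y0: float | None = None) -> GridTransform:
    return GridTransform(x0=x0, y0=nrow * CELL if y0 is None else y0, dx=CELL, dy=-CELL)


def raster(values, nodata: float = -9999.0, meaning: str = "") -> GridRaster:
    values = np.asarray(values, dtype=np.float64)
    return GridRaster(
        values=values, transform=transform(values.shape[0]), nodata=nodata, band_meaning=meaning
    )


@pytest.fixture
def flat_dem():
    return raster(np.full((10, 10), 100.0), meaning="elevation m")


@pytest.fixture
def tmp_tif(tmp_path):
    return tmp_path / "r.tif"
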