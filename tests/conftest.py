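import numpy as np
import pytest

from recpot import (
    INDICATOR_CODES,
    INDICATOR_POLARITY,
    GridTransform,
    IndicatorLayer,
    IndicatorStack,
    LandscapeConfig,
    RasterGrid,
    generate_landscape,
)

CRS = "SYNTH:METRIC"


def make_grid(values, cell_size=1000.0, mask=None, crs=CRS, x0=0.0):
    values = np.asarray(values, dtype=float)
    t = GridTransform(x_origin=x0, y_origin=values.shape[0] * cell_size, cell_size=cell_size)
    return RasterGrid(values=values, transform=t, nodata_mask=mask, crs_id=crs)


def make_layer(code, values, cell_size=1000.0, mask=None):
    return IndicatorLayer(
        code=code,
        polarity=INDICATOR_POLARITY[code],
        grid=make_grid(values, cell_size=cell_size, mask=mask),
    )


def full_stack(shape=(6, 6), epoch="2000", seed=0, overrides=None):
    """A 15-code stack of random positive layers, with per-code overrides."""
    rng = np.random.default_rng(seed)
    overrides = overrides or {}
    layers = {}
    for code in INDICATOR_CODES:
        vals = overrides.get(code)
        if vals is None:
            vals = rng.uniform(0.0, 10.0, size=shape)
        layers[code] = make_layer(code, vals)
    return IndicatorStack(epoch=epoch, layers=layers)


@pytest.fixture(scope="session")
def mini_landscape():
    """A small but complete synthetic landscape shared across tests."""
    cfg = LandscapeConfig(shape=(60, 60), seed=7, epochs=("2000", "2020"))
    return generate_landscape(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
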