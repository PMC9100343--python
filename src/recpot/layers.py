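"""Indicator layers and aligned stacks.

The evaluation system uses a closed registry of 15 indicators, each with a
fixed polarity: positive indicators raise recreation potential as they grow,
negative indicators lower it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid, resample

__all__ = [
    "INDICATOR_POLARITY",
    "INDICATOR_CODES",
    "POSITIVE",
    "NEGATIVE",
    "IndicatorLayer",
    "IndicatorStack",
    "align_stack",
]

POSITIVE = "positive"
NEGATIVE = "negative"

#: Closed registry: indicator code -> polarity.
INDICATOR_POLARITY: dict[str, str] = {
    "SHDI": POSITIVE,   # landscape diversity
    "RDLS": POSITIVE,   # landscape heterogeneity / relief
    "HQ": POSITIVE,     # biodiversity (habitat quality)
    "DTPA": NEGATIVE,   # distance to protected areas
    "NDVI": POSITIVE,   # vegetation coverage
    "DTL": NEGATIVE,    # distance to lakes
    "DTR": NEGATIVE,    # distance to rivers
    "DTG": NEGATIVE,    # distance to glaciers
    "OC": POSITIVE,     # oxygen content
    "PRRI": NEGATIVE,   # plateau (altitude sickness) reaction risk index
    "TEM": POSITIVE,    # mean annual temperature
    "PRE": POSITIVE,    # mean annual precipitation
    "TNI": NEGATIVE,    # terrain niche index
    "DTC": NEGATIVE,    # distance to county
    "TA": NEGATIVE,     # transport accessibility (travel time, hours)
}

INDICATOR_CODES: tuple[str, ...] = tuple(INDICATOR_POLARITY)


@dataclass
class IndicatorLayer:
    """One named indicator raster with its polarity."""

    code: str
    polarity: str
    grid: RasterGrid
    units: str = ""

    def __post_init__(self) -> None:
        if self.code not in INDICATOR_POLARITY:
            raise ValueError(
                f"unknown indicator code {self.code!r}; "
                f"expected one of {sorted(INDICATOR_POLARITY)}"
            )
        expected = INDICATOR_POLARITY[self.code]
        if self.polarity != expected:
            raise ValueError(
                f"indicator {self.code} is a {expected} indicator, "
                f"got polarity {self.polarity!r}"
            )


@dataclass
class IndicatorStack:
    """Co-registered indicator layers for one epoch.

    A full evaluation stack holds all 15 codes; partial stacks are allowed
    for intermediate work, and the overlay stage enforces completeness.
    """

    epoch: str
    layers: dict[str, IndicatorLayer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = {}
        for code in INDICATOR_CODES:
            if code in self.layers:
                ordered[code] = self.layers[code]
        extra = set(self.layers) - set(ordered)
        if extra:
            raise ValueError(f"unknown indicator codes in stack: {sorted(extra)}")
        self.layers = ordered
        grids = [lyr.grid for lyr in self.layers.values()]
        for g in grids[1:]:
            if not g.same_grid(grids[0]):
                raise ValueError("stack layers do not share shape/transform/CRS")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values())).grid

    def is_complete(self) -> bool:
        return set(self.layers) == set(INDICATOR_CODES)

    def common_valid(self) -> np.ndarray:
        """True where every layer holds data (union-of-nodata convention)."""
        valid = np.ones(self.template.shape, dtype=bool)
        for lyr in self.layers.values():
            valid &= lyr.grid.valid
        return valid

    def __getitem__(self, code: str) -> IndicatorLayer:
        return self.layers[code]

    def __iter__(self):
        return iter(self.layers.values())


def align_stack(
    layers: list[IndicatorLayer],
    template: RasterGrid,
    resampling: str = "nearest",
    epoch: str = "",
    categorical: set[str] | frozenset[str] = frozenset(),
) -> IndicatorStack:
    """Resample every layer onto ``template`` and union the nodata masks.

    Codes listed in ``categorical`` must use nearest resampling. Cells masked
    in any input end up masked in every output layer, so downstream overlay is
    only defined where all indicators are.
    """
    if resampling == "bilinear":
        bad = [l.code for l in layers if l.code in categorical]
        if bad:
            raise ValueError(
                f"categorical layers {bad} cannot be resampled bilinearly"
            )
    aligned = {
        l.code: IndicatorLayer(
            code=l.code,
            polarity=l.polarity,
            grid=resample(l.grid, template, method=resampling),
            units=l.units,
        )
        for l in layers
    }
    union_mask = np.zeros(template.shape, dtype=bool)
    for lyr in aligned.values():
        union_mask |= lyr.grid.nodata_mask
    for lyr in aligned.values():
        g = lyr.grid
        vals = np.array(g.values, dtype=float)
        vals[union_mask] = np.nan
        lyr.grid = RasterGrid(
            values=vals,
            transform=g.transform,
            nodata_mask=union_mask.copy(),
            crs_id=g.crs_id,
        )
    return IndicatorStack(epoch=epoch, layers=aligned)
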