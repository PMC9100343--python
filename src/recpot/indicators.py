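"""Formula-level indicator computations.

Two indicator families are computed here from primary data: Shannon
landscape-diversity maps over a categorical land-cover grid, and Euclidean
distance-to-feature layers. Every other indicator of the evaluation system
(RDLS, HQ, NDVI, OC, PRRI, TEM, PRE, TNI, TA) is produced by external models
and enters the stack through :func:`register_external_layer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import uniform_filter
from shapely.strtree import STRtree

from .grid import RasterGrid
from .layers import INDICATOR_POLARITY, IndicatorLayer
from .vector import FeatureSet

__all__ = [
    "LandCoverGrid",
    "shdi_map",
    "distance_layer",
    "register_external_layer",
]


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster with an integer-code legend."""

    grid: RasterGrid
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid]
        if self.legend:
            codes = set(np.unique(vals.astype(int)))
            unknown = codes - set(self.legend)
            if unknown:
                raise ValueError(f"land-cover codes missing from legend: {sorted(unknown)}")

    def classes(self) -> np.ndarray:
        return np.unique(self.grid.values[self.grid.valid].astype(int))


def _box_sum(a: np.ndarray, radius: int) -> np.ndarray:
    size = 2 * radius + 1
    # uniform_filter averages; multiply back to get window sums (reflect edges
    # would double-count, so pad with zeros via 'constant')
    return uniform_filter(a, size=size, mode="constant", cval=0.0) * size**2


def shdi_map(lc: LandCoverGrid, window_radius_cells: int = 5) -> RasterGrid:
    """Per-cell Shannon diversity of land cover in a square moving window.

    SHDI = -Σ_k p_k ln p_k over the valid cells of the (2r+1)² window;
    a single-class window scores 0 and an all-nodata window is nodata.
    """
    if window_radius_cells < 1:
        raise ValueError("window radius must be >= 1")
    g = lc.grid
    valid = g.valid.astype(float)
    n_valid = _box_sum(valid, window_radius_cells)

    shannon = np.zeros(g.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in lc.classes():
            indicator = ((g.values == k) & g.valid).astype(float)
            count = _box_sum(indicator, window_radius_cells)
            p = np.where(n_valid > 0, count / np.maximum(n_valid, 1), 0.0)
            shannon -= np.where(p > 0, p * np.log(p), 0.0)
    # box sums are float; clamp counting noise so monomorphic windows hit 0
    shannon = np.where(shannon < 1e-7, 0.0, shannon)
    mask = (n_valid < 0.5) | g.nodata_mask
    shannon[mask] = np.nan
    return RasterGrid(
        values=shannon, transform=g.transform, nodata_mask=mask, crs_id=g.crs_id
    )


def distance_layer(features: FeatureSet, template: RasterGrid) -> RasterGrid:
    """Exact Euclidean distance (m) from each cell center to the nearest feature."""
    if len(features.geometries) == 0:
        raise ValueError("empty feature set")
    if features.crs_id and template.crs_id and features.crs_id != template.crs_id:
        raise ValueError(
            f"feature CRS {features.crs_id!r} != grid CRS {template.crs_id!r}"
        )
    x, y = template.cell_centers()
    pts = shapely.points(x.ravel(), y.ravel())
    tree = STRtree(features.geometries)
    nearest = tree.nearest(pts)
    geoms = np.asarray(features.geometries, dtype=object)
    dist = shapely.distance(pts, geoms[nearest]).reshape(template.shape)
    dist[template.nodata_mask] = np.nan
    return RasterGrid(
        values=dist,
        transform=template.transform,
        nodata_mask=template.nodata_mask.copy(),
        crs_id=template.crs_id,
    )


def register_external_layer(code: str, grid: RasterGrid, polarity: str, units: str = "") -> IndicatorLayer:
    """Wrap an externally computed raster as a registry indicator.

    The declared polarity must match the registry's fixed annotation for the
    code; the grid itself passes through unmodified.
    """
    if code not in INDICATOR_POLARITY:
        raise ValueError(
            f"unknown indicator code {code!r}; expected one of {sorted(INDICATOR_POLARITY)}"
        )
    return IndicatorLayer(code=code, polarity=polarity, grid=grid, units=units)
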