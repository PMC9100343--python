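"""Vector features (GeoJSON via shapely) and zone rasterization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grid import RasterGrid

__all__ = ["FeatureSet", "ZoneSet", "read_geojson", "write_geojson"]


@dataclass
class FeatureSet:
    """A named collection of geometries sharing the grid's projected CRS."""

    name: str
    geometries: list
    crs_id: str = ""

    def __post_init__(self) -> None:
        if len(self.geometries) == 0:
            raise ValueError(f"feature set {self.name!r} is empty")


def write_geojson(fs: FeatureSet, path) -> None:
    doc = {
        "type": "FeatureCollection",
        "name": fs.name,
        "crs_id": fs.crs_id,
        "features": [
            {"type": "Feature", "properties": {"name": fs.name}, "geometry": mapping(g)}
            for g in fs.geometries
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_geojson(path, name: str | None = None) -> FeatureSet:
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    return FeatureSet(
        name=name or doc.get("name", Path(path).stem),
        geometries=geoms,
        crs_id=doc.get("crs_id", ""),
    )


@dataclass
class ZoneSet:
    """Named boolean zone rasters co-registered with an analysis template."""

    template: RasterGrid
    zones: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nm, z in self.zones.items():
            z = np.asarray(z, dtype=bool)
            if z.shape != self.template.shape:
                raise ValueError(f"zone {nm!r} shape {z.shape} != template {self.template.shape}")
            self.zones[nm] = z

    def add_from_polygons(self, name: str, fs: FeatureSet) -> None:
        """Rasterize polygons by cell-center containment."""
        x, y = self.template.cell_centers()
        pts = shapely.points(x.ravel(), y.ravel())
        covered = np.zeros(pts.shape, dtype=bool)
        for geom in fs.geometries:
            covered |= shapely.intersects(geom, pts)
        self.zones[name] = covered.reshape(self.template.shape)

    def names(self) -> list[str]:
        return list(self.zones)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.zones[name]
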