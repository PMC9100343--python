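"""Gridded raster primitives and plain-text raster I/O.

Rasters live on a north-up, cell-center-registered grid in a projected CRS
with square cells; all distances are in meters and areas in km². On disk a
raster is an ESRI ASCII grid (``.asc``) with a ``.prj`` sidecar carrying the
CRS identifier — a deliberately text-only interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridTransform",
    "RasterGrid",
    "read_raster",
    "write_raster",
    "resample",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of a north-up grid with square cells.

    ``x_origin``/``y_origin`` locate the outer corner of cell (0, 0) — the
    west edge and the north edge. Row 0 is the northernmost row.
    """

    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell size must be > 0, got {self.cell_size}")

    def cell_center(self, row, col):
        """Projected (x, y) of cell centers; accepts scalars or arrays."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def is_close(self, other: "GridTransform", tol: float = 1e-6) -> bool:
        return (
            abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class RasterGrid:
    """A single-band raster: values + nodata mask + georeference.

    ``nodata_mask`` is True where the cell is missing; every operation in the
    package ignores masked cells.
    """

    values: np.ndarray
    transform: GridTransform
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                f"nodata_mask shape {self.nodata_mask.shape} != values shape "
                f"{self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def same_grid(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.transform.is_close(other.transform, tol)
            and self.crs_id == other.crs_id
        )

    def copy_with(self, values: np.ndarray, nodata_mask=None) -> "RasterGrid":
        return RasterGrid(
            values=np.array(values),
            transform=self.transform,
            nodata_mask=(
                self.nodata_mask.copy() if nodata_mask is None else np.array(nodata_mask)
            ),
            crs_id=self.crs_id,
        )

    def cell_centers(self):
        """(x, y) arrays of shape ``self.shape`` with all cell centers."""
        rows, cols = np.indices(self.shape)
        return self.transform.cell_center(rows, cols)


def _prj_path(path: Path) -> Path:
    return path.with_suffix(".prj")


def write_raster(grid: RasterGrid, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write ``grid`` as an ESRI ASCII grid plus a ``.prj`` CRS sidecar."""
    path = Path(path)
    nrows, ncols = grid.shape
    t = grid.transform
    yll = t.y_origin - nrows * t.cell_size
    vals = np.array(grid.values, dtype=float)
    vals[grid.nodata_mask] = nodata
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {t.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {t.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")  # lossless float64 round trip
    _prj_path(path).write_text(grid.crs_id + "\n")


def read_raster(path) -> RasterGrid:
    """Read an ESRI ASCII grid; the ``.prj`` sidecar must declare the CRS."""
    path = Path(path)
    prj = _prj_path(path)
    if not prj.exists():
        raise FileNotFoundError(
            f"raster {path} has no CRS: expected sidecar {prj}"
        )
    crs_id = prj.read_text().strip()
    if not crs_id:
        raise ValueError(f"raster {path} has an empty CRS sidecar {prj}")

    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)

    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"raster {path}: malformed header, missing {sorted(missing)}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(
            f"raster {path}: data shape {vals.shape} != header ({nrows}, {ncols})"
        )
    cs = header["cellsize"]
    transform = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cs,
        cell_size=cs,
    )
    if "nodata_value" in header:
        mask = vals == header["nodata_value"]
    else:
        mask = np.zeros_like(vals, dtype=bool)
    return RasterGrid(values=vals, transform=transform, nodata_mask=mask, crs_id=crs_id)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def resample(grid: RasterGrid, template: RasterGrid, method: str = "nearest") -> RasterGrid:
    """Resample ``grid`` onto ``template``'s shape and transform.

    ``nearest`` picks the source cell containing each template cell center;
    ``bilinear`` interpolates between the four surrounding source cell
    centers, propagating nodata from any contributing cell. Both grids must
    share a CRS; a template whose cell centers all fall outside the source
    extent is an error.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if grid.crs_id != template.crs_id:
        raise ValueError(
            f"CRS mismatch: {grid.crs_id!r} vs template {template.crs_id!r}"
        )
    if grid.same_grid(template):
        return grid.copy_with(grid.values)

    st = grid.transform
    nrows_s, ncols_s = grid.shape
    x, y = template.cell_centers()
    # fractional source index of each template cell center (cell-center space)
    fc = (x - st.x_origin) / st.cell_size - 0.5
    fr = (st.y_origin - y) / st.cell_size - 0.5

    inside = (fc > -0.5) & (fc < ncols_s - 0.5) & (fr > -0.5) & (fr < nrows_s - 0.5)
    if not inside.any():
        raise ValueError("source raster does not overlap the template extent")

    if method == "nearest":
        ri = np.clip(np.rint(fr).astype(int), 0, nrows_s - 1)
        ci = np.clip(np.rint(fc).astype(int), 0, ncols_s - 1)
        out = grid.values[ri, ci].astype(float)
        mask = grid.nodata_mask[ri, ci] | ~inside
    else:
        r0 = np.clip(np.floor(fr).astype(int), 0, nrows_s - 1)
        c0 = np.clip(np.floor(fc).astype(int), 0, ncols_s - 1)
        r1 = np.clip(r0 + 1, 0, nrows_s - 1)
        c1 = np.clip(c0 + 1, 0, ncols_s - 1)
        wr = np.clip(fr - r0, 0.0, 1.0)
        wc = np.clip(fc - c0, 0.0, 1.0)
        v = grid.values.astype(float)
        out = (
            v[r0, c0] * (1 - wr) * (1 - wc)
            + v[r0, c1] * (1 - wr) * wc
            + v[r1, c0] * wr * (1 - wc)
            + v[r1, c1] * wr * wc
        )
        m = grid.nodata_mask
        mask = (m[r0, c0] | m[r0, c1] | m[r1, c0] | m[r1, c1]) | ~inside

    out[mask] = np.nan
    return RasterGrid(
        values=out,
        transform=template.transform,
        nodata_mask=mask,
        crs_id=template.crs_id,
    )
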