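"""Synthetic landscape generation for end-to-end pipeline testing.

Everything a run needs is generated here with controlled statistical
structure and a recorded ground truth:

* a DEM rising along the SE→NW diagonal plus a smooth correlated field;
* 15 co-registered indicator layers per epoch — continuous indicators are
  smooth Gaussian-filtered fields with configured linear elevation loadings
  (temperature, precipitation, oxygen and vegetation decline with elevation;
  altitude-sickness risk and the terrain niche index rise) and an extra
  piecewise "kink" loading above a planted elevation threshold T, so the
  integrated index inherits a breakpoint at T;
* categorical land cover from elevation-niche class mixtures (more diverse at
  low elevation), from which the diversity indicator is computed;
* point/line/polygon features (lakes, rivers, glaciers, counties, protected
  areas) feeding the distance layers;
* zones: protected/non-protected and the SE/NW halves of the diagonal
  division line.

All randomness descends from a single seed through spawned child generators,
so identical configs give bit-identical landscapes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .grid import GridTransform, RasterGrid
from .index import PotentialMap
from .indicators import LandCoverGrid, distance_layer, shdi_map
from .layers import INDICATOR_POLARITY, IndicatorLayer, IndicatorStack
from .vector import FeatureSet, ZoneSet

__all__ = [
    "LandscapeConfig",
    "LandscapeTruth",
    "SyntheticLandscape",
    "generate_landscape",
    "expected_truth",
    "planted_potential",
    "LAND_COVER_LEGEND",
]

LAND_COVER_LEGEND = {
    1: "water", 2: "forest", 3: "shrubland", 4: "grassland", 5: "bareland", 6: "ice",
}

# elevation niches (center km, width km, prior) controlling class mixtures
_CLASS_NICHES = {
    1: (1.6, 0.8, 0.0),
    2: (1.9, 0.7, 0.2),
    3: (2.5, 0.7, 0.2),
    4: (3.2, 0.9, 0.3),
    5: (4.2, 0.9, 0.4),
    6: (4.8, 0.5, 0.3),
}

# per-code (base, linear loading per km, kink loading per km above T, field sd)
# linear terms keep the climatic SE->NW gradients mild below the threshold;
# the kink terms carry most of the post-threshold decline
_DEFAULT_LOADINGS: dict[str, tuple[float, float, float, float]] = {
    "RDLS": (400.0, 0.0, 0.0, 120.0),
    "HQ": (0.70, -0.02, -0.18, 0.06),
    "NDVI": (0.85, -0.03, -0.25, 0.05),
    "OC": (300.0, -10.0, -70.0, 8.0),
    "PRRI": (10.0, 5.0, 30.0, 3.0),
    "TEM": (14.0, -1.5, -6.0, 1.2),
    "PRE": (800.0, -40.0, -250.0, 60.0),
    "TNI": (0.6, 0.06, 0.35, 0.08),
    "TA": (1.5, 0.4, 2.5, 0.6),
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Generative parameters of a synthetic landscape."""

    shape: tuple[int, int] = (120, 120)
    cell_size_m: float = 1000.0
    crs_id: str = "SYNTH:METRIC"
    epochs: tuple[str, ...] = ("2000", "2010", "2020")
    corr_length_cells: float = 8.0
    elevation_range_m: tuple[float, float] = (1000.0, 4500.0)
    dem_relief_m: float = 300.0
    threshold_m: float = 3000.0
    slope_pre_per_km: float = 0.02
    slope_post_per_km: float = -0.30
    base_potential: float = 0.65
    noise_sigma: float = 0.03
    n_lakes: int = 12
    n_rivers: int = 4
    n_glaciers: int = 8
    n_counties: int = 10
    n_protected_areas: int = 6
    protected_fraction: float = 0.2
    shdi_window_radius: int = 5
    loadings: dict = field(default_factory=dict)  # per-code overrides
    epoch_drift: float = 0.05  # fractional loading drift per decade
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range_m
        if not (hi > lo > 0):
            raise ValueError("elevation range must be positive and increasing")
        if not lo <= self.threshold_m <= hi:
            raise ValueError("planted threshold must lie inside the elevation range")
        if not 0 < self.protected_fraction < 1:
            raise ValueError("protected fraction must be in (0, 1)")
        if self.corr_length_cells <= 0 or self.cell_size_m <= 0:
            raise ValueError("lengths must be > 0")
        max_features = self.shape[0] * self.shape[1] // 4
        for nm in ("n_lakes", "n_rivers", "n_glaciers", "n_counties", "n_protected_areas"):
            v = getattr(self, nm)
            if v < 1 or v > max_features:
                raise ValueError(f"{nm}={v} infeasible for grid {self.shape}")

    def resolved_loadings(self) -> dict[str, tuple[float, float, float, float]]:
        out = dict(_DEFAULT_LOADINGS)
        out.update(self.loadings)
        return out


@dataclass
class LandscapeTruth:
    """The planted generative parameters, for parameter-recovery assertions."""

    threshold_m: float
    slope_pre_per_km: float
    slope_post_per_km: float
    base_potential: float
    noise_sigma: float
    loadings: dict
    class_niches: dict
    epochs: tuple[str, ...]
    seed: int
    config: dict


@dataclass
class SyntheticLandscape:
    config: LandscapeConfig
    dem: RasterGrid
    stacks: dict[str, IndicatorStack]
    landcover: dict[str, LandCoverGrid]
    features: dict[str, FeatureSet]
    zones: ZoneSet
    truth: LandscapeTruth


def expected_truth(cfg: LandscapeConfig) -> LandscapeTruth:
    return LandscapeTruth(
        threshold_m=cfg.threshold_m,
        slope_pre_per_km=cfg.slope_pre_per_km,
        slope_post_per_km=cfg.slope_post_per_km,
        base_potential=cfg.base_potential,
        noise_sigma=cfg.noise_sigma,
        loadings=cfg.resolved_loadings(),
        class_niches=dict(_CLASS_NICHES),
        epochs=cfg.epochs,
        seed=cfg.seed,
        config=asdict(cfg),
    )


def config_from_truth(truth: LandscapeTruth) -> LandscapeConfig:
    """Rebuild the generating config from a truth record (round trip)."""
    d = dict(truth.config)
    d["shape"] = tuple(d["shape"])
    d["epochs"] = tuple(d["epochs"])
    d["elevation_range_m"] = tuple(d["elevation_range_m"])
    return LandscapeConfig(**d)


def gaussian_field(shape, corr_length: float, rng) -> np.ndarray:
    """Unit-variance smooth field: Gaussian-filtered white noise."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=corr_length, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _diag_coord(shape) -> np.ndarray:
    """0 at the SE corner, 1 at the NW corner (row 0 = north)."""
    nr, nc = shape
    r, c = np.indices(shape)
    return ((nr - 1 - r) + (nc - 1 - c)) / max(nr + nc - 2, 1)


def _hinge_km(dem_m: np.ndarray, threshold_m: float) -> np.ndarray:
    return np.maximum(dem_m - threshold_m, 0.0) / 1000.0


def _make_dem(cfg: LandscapeConfig, rng) -> RasterGrid:
    lo, hi = cfg.elevation_range_m
    u = _diag_coord(cfg.shape)
    f = gaussian_field(cfg.shape, cfg.corr_length_cells, rng)
    dem = lo + u * (hi - lo) + f * cfg.dem_relief_m
    dem = np.clip(dem, lo, hi)
    t = GridTransform(x_origin=0.0, y_origin=cfg.shape[0] * cfg.cell_size_m,
                      cell_size=cfg.cell_size_m)
    return RasterGrid(values=dem, transform=t, crs_id=cfg.crs_id)


def _make_landcover(cfg: LandscapeConfig, dem: RasterGrid, rng, epoch_idx: int) -> LandCoverGrid:
    e_km = dem.values / 1000.0
    shift = 0.05 * epoch_idx  # niches creep upward over decades
    logits = np.stack(
        [
            prior - (e_km - (center + shift)) ** 2 / (2.0 * width**2)
            for center, width, prior in _CLASS_NICHES.values()
        ]
    )
    p = np.exp(logits - logits.max(axis=0))
    p /= p.sum(axis=0)
    cum = np.cumsum(p, axis=0)
    u = rng.random(dem.shape)
    cls = (u[None] > cum).sum(axis=0) + 1
    return LandCoverGrid(
        grid=RasterGrid(values=cls.astype(float), transform=dem.transform,
                        crs_id=dem.crs_id),
        legend=dict(LAND_COVER_LEGEND),
    )


def _sample_cells(weight: np.ndarray, k: int, rng) -> list[tuple[int, int]]:
    p = np.clip(weight, 0, None).ravel()
    p = p / p.sum()
    idx = rng.choice(p.size, size=k, replace=False, p=p)
    rows, cols = np.unravel_index(idx, weight.shape)
    return list(zip(rows.tolist(), cols.tolist()))


def _make_features(cfg: LandscapeConfig, dem: RasterGrid, attractiveness: np.ndarray, rng) -> dict[str, FeatureSet]:
    e = dem.values
    lo, hi = cfg.elevation_range_m
    low_pref = (hi - e) / (hi - lo) + 0.05
    high_pref = (e - lo) / (hi - lo) + 0.05
    cs = cfg.cell_size_m

    def centers(cells):
        return [dem.transform.cell_center(r, c) for r, c in cells]

    lakes = [
        Point(x, y).buffer(rng.uniform(0.8, 2.5) * cs)
        for x, y in centers(_sample_cells(low_pref**2, cfg.n_lakes, rng))
    ]
    glaciers = [
        Point(x, y).buffer(rng.uniform(0.8, 2.0) * cs)
        for x, y in centers(_sample_cells(high_pref**3, cfg.n_glaciers, rng))
    ]
    counties = [Point(x, y) for x, y in centers(_sample_cells(low_pref**3, cfg.n_counties, rng))]

    smooth_dem = gaussian_filter(e, sigma=3.0, mode="reflect")
    rivers = []
    for r0, c0 in _sample_cells(high_pref, cfg.n_rivers, rng):
        path = [(r0, c0)]
        r, c = r0, c0
        for _ in range(max(cfg.shape) * 2):
            window = [
                (rr, cc)
                for rr in range(max(r - 1, 0), min(r + 2, cfg.shape[0]))
                for cc in range(max(c - 1, 0), min(c + 2, cfg.shape[1]))
                if (rr, cc) != (r, c)
            ]
            nxt = min(window, key=lambda rc: smooth_dem[rc])
            if smooth_dem[nxt] >= smooth_dem[r, c]:
                break
            r, c = nxt
            path.append((r, c))
        if len(path) >= 2:
            rivers.append(LineString(centers(path)))
    if not rivers:  # flat landscapes: fall back to a straight channel
        rivers.append(LineString(centers([(0, 0), (cfg.shape[0] - 1, cfg.shape[1] - 1)])))

    n_pa = cfg.n_protected_areas
    total_area = cfg.shape[0] * cfg.shape[1] * cs**2
    pa_radius = float(np.sqrt(cfg.protected_fraction * total_area / (n_pa * np.pi)))
    pas = [
        Point(x, y).buffer(pa_radius)
        for x, y in centers(_sample_cells(np.exp(3.0 * attractiveness), n_pa, rng))
    ]

    crs = cfg.crs_id
    return {
        "lakes": FeatureSet("lakes", lakes, crs),
        "rivers": FeatureSet("rivers", rivers, crs),
        "glaciers": FeatureSet("glaciers", glaciers, crs),
        "counties": FeatureSet("counties", counties, crs),
        "protected_areas": FeatureSet("protected_areas", pas, crs),
    }


def generate_landscape(cfg: LandscapeConfig) -> SyntheticLandscape:
    """Generate the complete, reproducible input bundle for one landscape."""
    ss = np.random.SeedSequence(cfg.seed)
    keys = ["dem", "landcover", "features", "fields", "noise"]
    child = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    dem = _make_dem(cfg, child["dem"])
    e_km = dem.values / 1000.0
    hinge = _hinge_km(dem.values, cfg.threshold_m)
    loadings = cfg.resolved_loadings()

    # persistent spatial fields per continuous code (shared across epochs)
    fields = {code: gaussian_field(cfg.shape, cfg.corr_length_cells, child["fields"])
              for code in loadings}

    # attractiveness guiding protected-area placement: where HQ + NDVI end up high
    def raw_layer(code, epoch_idx):
        base, lin, kink, sd = loadings[code]
        drift = 1.0 + cfg.epoch_drift * epoch_idx
        vals = base + lin * drift * e_km + kink * drift * hinge + sd * fields[code]
        if code in ("HQ", "NDVI"):
            vals = np.clip(vals, 0.0, 1.0)
        if code in ("TA", "RDLS", "OC", "PRE", "PRRI"):
            vals = np.maximum(vals, 0.0)
        return vals

    hq0, nd0 = raw_layer("HQ", 0), raw_layer("NDVI", 0)
    attract = (hq0 - hq0.mean()) / (hq0.std() + 1e-12) + (nd0 - nd0.mean()) / (nd0.std() + 1e-12)

    features = _make_features(cfg, dem, attract, child["features"])

    dist_codes = {
        "DTPA": "protected_areas", "DTL": "lakes", "DTR": "rivers",
        "DTG": "glaciers", "DTC": "counties",
    }
    dist_layers = {
        code: distance_layer(features[fname], dem)
        for code, fname in dist_codes.items()
    }

    stacks: dict[str, IndicatorStack] = {}
    landcover: dict[str, LandCoverGrid] = {}
    for i, epoch in enumerate(cfg.epochs):
        lc = _make_landcover(cfg, dem, child["landcover"], i)
        landcover[epoch] = lc
        shdi = shdi_map(lc, cfg.shdi_window_radius)
        layers = {"SHDI": IndicatorLayer("SHDI", INDICATOR_POLARITY["SHDI"], shdi)}
        for code in loadings:
            grid = RasterGrid(values=raw_layer(code, i), transform=dem.transform,
                              crs_id=dem.crs_id)
            layers[code] = IndicatorLayer(code, INDICATOR_POLARITY[code], grid)
        for code, dgrid in dist_layers.items():
            layers[code] = IndicatorLayer(code, INDICATOR_POLARITY[code],
                                          dgrid.copy_with(dgrid.values))
        stacks[epoch] = IndicatorStack(epoch=epoch, layers=layers)

    zones = ZoneSet(template=dem)
    zones.add_from_polygons("PA", features["protected_areas"])
    zones.zones["NPA"] = ~zones.zones["PA"]
    u = _diag_coord(cfg.shape)
    zones.zones["SE_of_line"] = u < 0.5
    zones.zones["NW_of_line"] = u >= 0.5

    return SyntheticLandscape(
        config=cfg,
        dem=dem,
        stacks=stacks,
        landcover=landcover,
        features=features,
        zones=zones,
        truth=expected_truth(cfg),
    )


def planted_potential(dem: RasterGrid, cfg: LandscapeConfig, seed: int | None = None,
                      epoch: str = "") -> PotentialMap:
    """A potential surface with an exactly known elevation response.

    value = base + s_pre·min(e−T, 0)/1000 + s_post·max(e−T, 0)/1000 + ε,
    ε ~ N(0, σ), clipped to [0, 1] (defaults keep clipping inactive). This is
    the reference surface for breakpoint-recovery checks: the true breakpoint
    and segment slopes are the config's planted values.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    e = dem.values
    d_km = (e - cfg.threshold_m) / 1000.0
    resp = (
        cfg.base_potential
        + cfg.slope_pre_per_km * np.minimum(d_km, 0.0)
        + cfg.slope_post_per_km * np.maximum(d_km, 0.0)
    )
    vals = resp + rng.normal(0.0, cfg.noise_sigma, size=e.shape)
    vals = np.clip(vals, 0.0, 1.0)
    vals[dem.nodata_mask] = np.nan
    grid = dem.copy_with(vals)
    return PotentialMap(grid=grid, epoch=epoch, weights_used=None,
                        minmax_table={}, minmax_policy="planted")
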