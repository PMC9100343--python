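"""Standardization, weighted-overlay potential index, level classification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import minimize_scalar

from .grid import RasterGrid
from .layers import NEGATIVE, POSITIVE, IndicatorLayer, IndicatorStack

if TYPE_CHECKING:  # avoid circular import; weights.py imports standardize
    from .weights import WeightSet

__all__ = [
    "PotentialMap",
    "ClassMap",
    "standardize",
    "pooled_minmax",
    "compute_inrpi",
    "classify",
    "DEFAULT_LEVEL_LABELS",
]

DEFAULT_LEVEL_LABELS = (
    "very low potential",
    "low potential",
    "moderate potential",
    "high potential",
    "very high potential",
)


def standardize(
    layer: IndicatorLayer, minmax: tuple[float, float] | None = None
) -> RasterGrid:
    """Min-max standardize a layer to [0, 1], respecting polarity.

    Positive indicators map min→0, max→1; negative indicators map min→1,
    max→0, so that larger standardized values always mean higher potential.
    If ``minmax`` is supplied (e.g. pooled across epochs), values outside the
    range clip to [0, 1]; otherwise the range is the layer's own valid range.
    """
    g = layer.grid
    if minmax is None:
        vv = g.valid_values()
        if vv.size == 0:
            raise ValueError(f"layer {layer.code}: no valid cells")
        lo, hi = float(vv.min()), float(vv.max())
        if hi <= lo:
            raise ValueError(
                f"layer {layer.code} is constant ({lo!r}); supply an explicit minmax"
            )
    else:
        lo, hi = float(minmax[0]), float(minmax[1])
        if hi <= lo:
            raise ValueError(f"layer {layer.code}: minmax must satisfy max > min")
    with np.errstate(invalid="ignore"):
        xs = (np.asarray(g.values, dtype=float) - lo) / (hi - lo)
    if layer.polarity == NEGATIVE:
        xs = 1.0 - xs
    elif layer.polarity != POSITIVE:
        raise ValueError(f"unknown polarity {layer.polarity!r}")
    xs = np.clip(xs, 0.0, 1.0)
    xs[g.nodata_mask] = np.nan
    return g.copy_with(xs)


def pooled_minmax(stacks) -> dict[str, tuple[float, float]]:
    """Per-code (min, max) pooled over every stack (epochs on a common scale)."""
    table: dict[str, tuple[float, float]] = {}
    for stack in stacks:
        for lyr in stack:
            vv = lyr.grid.valid_values()
            if vv.size == 0:
                continue
            lo, hi = float(vv.min()), float(vv.max())
            if lyr.code in table:
                plo, phi = table[lyr.code]
                table[lyr.code] = (min(plo, lo), max(phi, hi))
            else:
                table[lyr.code] = (lo, hi)
    return table


@dataclass
class PotentialMap:
    """The integrated potential surface for one epoch, valued in [0, 1]."""

    grid: RasterGrid
    epoch: str
    weights_used: "WeightSet | None" = None
    minmax_table: dict[str, tuple[float, float]] = field(default_factory=dict)
    minmax_policy: str = "per_epoch"

    def mean(self) -> float:
        return float(np.mean(self.grid.valid_values()))


def compute_inrpi(
    stack: IndicatorStack,
    weights: "WeightSet",
    minmax_policy: str = "global",
    minmax: dict[str, tuple[float, float]] | None = None,
) -> PotentialMap:
    """Weighted overlay: per cell, the index is Σ_j w_j · Xs_j.

    ``minmax_policy="global"`` (the default, for cross-epoch comparability)
    requires a pooled ``minmax`` table (see :func:`pooled_minmax`);
    ``"per_epoch"`` derives each layer's range from this stack alone. Cells
    missing any indicator are nodata.
    """
    if weights.kind != "combined":
        raise ValueError(f"expected combined-kind weights, got {weights.kind!r}")
    missing = set(weights.codes) - set(stack.codes)
    if missing:
        raise ValueError(f"stack is missing indicators: {sorted(missing)}")
    if not stack.is_complete():
        raise ValueError(
            f"stack must carry all 15 indicators; has {len(stack.codes)}"
        )
    if minmax_policy == "global":
        if minmax is None:
            raise ValueError(
                "minmax_policy='global' needs a pooled minmax table "
                "(compute it with pooled_minmax over all epochs)"
            )
    elif minmax_policy == "per_epoch":
        minmax = minmax or {}
    else:
        raise ValueError(f"unknown minmax_policy {minmax_policy!r}")

    valid = stack.common_valid()
    acc = np.zeros(stack.template.shape, dtype=float)
    used: dict[str, tuple[float, float]] = {}
    for code in weights.codes:
        lyr = stack[code]
        mm = minmax.get(code)
        if mm is None:
            vv = lyr.grid.valid_values()
            mm = (float(vv.min()), float(vv.max()))
        used[code] = mm
        xs = standardize(lyr, minmax=mm)
        acc += weights[code] * np.nan_to_num(xs.values, nan=0.0)
    acc = np.clip(acc, 0.0, 1.0)
    acc[~valid] = np.nan
    grid = RasterGrid(
        values=acc,
        transform=stack.template.transform,
        nodata_mask=~valid,
        crs_id=stack.template.crs_id,
    )
    return PotentialMap(
        grid=grid,
        epoch=stack.epoch,
        weights_used=weights,
        minmax_table=used,
        minmax_policy=minmax_policy,
    )


@dataclass
class ClassMap:
    """Ordinal level raster with its interior breakpoints.

    Level c covers [b_{c-1}, b_c) (left-closed, right-open); the top level is
    closed above.
    """

    grid: RasterGrid
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]
    epoch: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.breakpoints, dtype=float)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need exactly K labels for K-1 breakpoints")

    @property
    def K(self) -> int:
        return len(self.labels)

    def level_areas_km2(self) -> dict[int, float]:
        cell = self.grid.transform.cell_area_km2()
        vals = self.grid.values[self.grid.valid].astype(int)
        counts = np.bincount(vals, minlength=self.K + 1)
        return {c: float(counts[c] * cell) for c in range(1, self.K + 1)}


def _geometric_breaks(lo: float, hi: float, g: float, K: int) -> np.ndarray:
    """Interior breaks whose class widths form a geometric series with ratio g."""
    k = np.arange(1, K)
    if abs(g - 1.0) < 1e-12:
        frac = k / K
    else:
        frac = (g**k - 1.0) / (g**K - 1.0)
    return lo + (hi - lo) * frac


def _within_class_sse(values: np.ndarray, breaks: np.ndarray) -> float:
    idx = np.digitize(values, breaks)
    sse = 0.0
    for c in range(len(breaks) + 1):
        v = values[idx == c]
        if v.size:
            sse += float(np.sum((v - v.mean()) ** 2))
    return sse


def fit_geometric_interval(values: np.ndarray, K: int) -> tuple[np.ndarray, float]:
    """Choose the geometric ratio g minimizing total within-class SSE.

    Coarse log-spaced scan then a bounded 1-D refinement; g → 1 recovers
    equal intervals.
    """
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("cannot classify a constant surface")

    def objective(log_g: float) -> float:
        return _within_class_sse(values, _geometric_breaks(lo, hi, np.exp(log_g), K))

    grid = np.linspace(-2.5, 2.5, 41)
    best = min(grid, key=objective)
    lo_b = max(best - 0.25, -3.0)
    hi_b = min(best + 0.25, 3.0)
    res = minimize_scalar(objective, bounds=(lo_b, hi_b), method="bounded")
    g = float(np.exp(res.x if res.fun <= objective(best) else best))
    return _geometric_breaks(lo, hi, g, K), g


def classify(
    pm: PotentialMap,
    mode: str = "geometric_interval",
    K: int = 5,
    fixed_breaks=None,
    labels=None,
) -> ClassMap:
    """Cut the potential surface into K ordinal levels.

    ``fixed`` mode bins by the supplied K-1 interior breaks;
    ``geometric_interval`` fits breaks whose widths form a geometric series,
    with the ratio chosen to minimize within-class squared deviation.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    vv = pm.grid.valid_values()
    if mode == "fixed":
        if fixed_breaks is None or len(fixed_breaks) != K - 1:
            raise ValueError(f"fixed mode needs exactly {K - 1} breaks")
        breaks = np.asarray(fixed_breaks, dtype=float)
        if vv.size and (breaks.min() < vv.min() or breaks.max() > vv.max()):
            warnings.warn(
                "some breakpoints fall outside the data range; empty classes allowed",
                stacklevel=2,
            )
    elif mode == "geometric_interval":
        breaks, _ = fit_geometric_interval(vv, K)
    else:
        raise ValueError(f"unknown classification mode {mode!r}")

    cls = np.digitize(pm.grid.values, breaks) + 1  # left-closed bins, top closed
    cls = cls.astype(float)
    cls[pm.grid.nodata_mask] = np.nan
    if labels is None:
        labels = DEFAULT_LEVEL_LABELS if K == 5 else tuple(f"L{i+1}" for i in range(K))
    grid = pm.grid.copy_with(cls)
    return ClassMap(
        grid=grid, breakpoints=tuple(breaks), labels=tuple(labels), epoch=pm.epoch
    )
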