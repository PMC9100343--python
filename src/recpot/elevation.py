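"""Elevation response of the potential index: sampling, breakpoint fit, bands.

The central tool is a continuity-constrained two-segment linear regression of
the index on elevation, fit by exhaustive search over candidate breakpoints
(every sampled elevation, optionally thinned to a grid step) with ordinary
least squares under the constraint that the segments join at the breakpoint.
Slopes are reported per 1000 m of elevation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid
from .index import PotentialMap

__all__ = ["SamplePairs", "BreakpointFit", "sample_points", "fit_breakpoint", "band_profile"]


@dataclass
class SamplePairs:
    """Random (elevation, index) pairs drawn from jointly valid cells."""

    elevation_m: np.ndarray
    inrpi: np.ndarray
    seed: int
    epoch: str = ""

    @property
    def n(self) -> int:
        return self.elevation_m.size


def sample_points(pm: PotentialMap, dem: RasterGrid, n: int, seed: int) -> SamplePairs:
    """Uniform sampling without replacement over jointly valid cells."""
    if dem.shape != pm.grid.shape:
        raise ValueError("DEM is not aligned to the potential map")
    valid = pm.grid.valid & dem.valid
    idx = np.flatnonzero(valid)
    if n > idx.size:
        raise ValueError(f"requested {n} points but only {idx.size} valid cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    r, c = np.unravel_index(chosen, pm.grid.shape)
    return SamplePairs(
        elevation_m=dem.values[r, c].astype(float),
        inrpi=pm.grid.values[r, c].astype(float),
        seed=seed,
        epoch=pm.epoch,
    )


@dataclass
class BreakpointFit:
    """A joined two-segment linear fit of index on elevation.

    ``slope_pre``/``slope_post`` are the segment slopes in index units per
    1000 m; ``slope_post_unconstrained`` is the plain OLS slope over points
    above the fitted breakpoint (no continuity constraint), also per 1000 m.
    ``material`` is False when the two-segment model improves on the single
    line by less than ``material_tol`` (relative SSE) — no material
    breakpoint.
    """

    breakpoint_m: float
    slope_pre: float
    slope_post: float
    intercept: float
    sse: float
    sse_single_line: float
    n: int
    slope_post_unconstrained: float
    material: bool
    material_tol: float


def _ols_line(e: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, SSE of a simple least-squares line."""
    A = np.column_stack([np.ones_like(e), e])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[1]), float(coef[0]), float(resid @ resid)


def fit_breakpoint(
    s: SamplePairs,
    grid_step_m: float | None = None,
    min_segment: int = 5,
    material_tol: float = 0.01,
) -> BreakpointFit:
    """Exhaustive-search continuous two-segment fit of index on elevation.

    For each candidate breakpoint c the model y = b0 + b1·e + b2·max(0, e−c)
    is solved in closed form from suffix sums (O(1) per candidate after an
    O(n log n) sort); the candidate minimizing total SSE wins. Candidates are
    the sampled elevations with at least ``min_segment`` points on each side,
    thinned to ``grid_step_m`` if given.
    """
    e = np.asarray(s.elevation_m, dtype=float)
    y = np.asarray(s.inrpi, dtype=float)
    n = e.size
    if n < 20:
        raise ValueError(f"need at least 20 points, got {n}")
    if np.ptp(e) == 0:
        raise ValueError("degenerate sample: all elevations are equal")

    order = np.argsort(e)
    e, y = e[order], y[order]

    cand = np.unique(e[min_segment : n - min_segment])
    if grid_step_m is not None:
        lo = np.ceil(cand.min() / grid_step_m) * grid_step_m
        cand = np.arange(lo, cand.max() + 1e-9, grid_step_m)
    if cand.size == 0:
        raise ValueError("no candidate breakpoints with enough points per side")

    # suffix sums over points strictly above each candidate
    first_above = np.searchsorted(e, cand, side="right")
    cs1 = np.concatenate([np.cumsum(np.ones_like(e)[::-1])[::-1], [0.0]])
    cse = np.concatenate([np.cumsum(e[::-1])[::-1], [0.0]])
    csee = np.concatenate([np.cumsum((e * e)[::-1])[::-1], [0.0]])
    csy = np.concatenate([np.cumsum(y[::-1])[::-1], [0.0]])
    csey = np.concatenate([np.cumsum((e * y)[::-1])[::-1], [0.0]])
    S1 = cs1[first_above]
    Se = cse[first_above]
    See = csee[first_above]
    Sy = csy[first_above]
    Sey = csey[first_above]

    T1, Te, Tee = float(n), e.sum(), (e * e).sum()
    Ty, Tey, Tyy = y.sum(), (e * y).sum(), (y * y).sum()
    c = cand
    Sh = Se - c * S1
    Shh = See - 2 * c * Se + c * c * S1
    Seh = See - c * Se
    Shy = Sey - c * Sy

    m = cand.size
    A = np.empty((m, 3, 3))
    A[:, 0, 0] = T1
    A[:, 0, 1] = A[:, 1, 0] = Te
    A[:, 0, 2] = A[:, 2, 0] = Sh
    A[:, 1, 1] = Tee
    A[:, 1, 2] = A[:, 2, 1] = Seh
    A[:, 2, 2] = Shh
    b = np.stack([np.full(m, Ty), np.full(m, Tey), Shy], axis=1)

    keep = S1 >= 2  # need spread in the hinge column
    beta = np.full((m, 3), np.nan)
    sse = np.full(m, np.inf)
    try:
        beta[keep] = np.linalg.solve(A[keep], b[keep][..., None])[..., 0]
    except np.linalg.LinAlgError:
        for i in np.flatnonzero(keep):
            beta[i], *_ = np.linalg.lstsq(A[i], b[i], rcond=None)
    ok = keep & np.isfinite(beta).all(axis=1)
    sse[ok] = Tyy - np.einsum("ij,ij->i", beta[ok], b[ok])

    best = int(np.argmin(sse))
    b0, b1, b2 = beta[best]
    bp = float(cand[best])
    best_sse = max(float(sse[best]), 0.0)

    _, _, sse_single = _ols_line(e, y)
    scale = float(np.mean(y * y)) * n
    if sse_single <= 1e-12 * max(scale, 1e-300):
        material = False  # already a perfect line: no breakpoint to speak of
    else:
        material = (sse_single - best_sse) / sse_single > material_tol

    above = e > bp
    slope_post_unc, _, _ = _ols_line(e[above], y[above]) if above.sum() >= 2 else (float("nan"), 0, 0)

    return BreakpointFit(
        breakpoint_m=bp,
        slope_pre=float(b1) * 1000.0,
        slope_post=float(b1 + b2) * 1000.0,
        intercept=float(b0),
        sse=best_sse,
        sse_single_line=sse_single,
        n=n,
        slope_post_unconstrained=slope_post_unc * 1000.0,
        material=bool(material),
        material_tol=material_tol,
    )


def band_profile(pm: PotentialMap, dem: RasterGrid, band_width_m: float = 50.0):
    """Area-weighted mean index per elevation band [k·w, (k+1)·w).

    Returns a DataFrame with band bounds, mean index, area (km²) and cell
    count; empty bands are omitted.
    """
    import pandas as pd

    if band_width_m <= 0:
        raise ValueError("band width must be > 0")
    if dem.shape != pm.grid.shape:
        raise ValueError("DEM is not aligned to the potential map")
    sel = pm.grid.valid & dem.valid
    e = dem.values[sel].astype(float)
    v = pm.grid.values[sel].astype(float)
    k = np.floor(e / band_width_m).astype(int)
    cell = pm.grid.transform.cell_area_km2()
    df = pd.DataFrame({"k": k, "v": v})
    agg = df.groupby("k")["v"].agg(["mean", "count"]).reset_index()
    return pd.DataFrame(
        {
            "band_low_m": agg["k"] * band_width_m,
            "band_high_m": (agg["k"] + 1) * band_width_m,
            "mean_inrpi": agg["mean"],
            "area_km2": agg["count"] * cell,
            "n_cells": agg["count"],
        }
    )
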