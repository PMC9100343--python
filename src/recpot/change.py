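"""Temporal change accounting and zonal contrasts.

Transition matrices cross-tabulate level membership between two epochs in
km²; zone summaries report area-weighted means and per-level area shares for
named zones (protected vs non-protected, either side of a division line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .index import ClassMap, PotentialMap
from .vector import ZoneSet

__all__ = ["TransitionMatrix", "ZoneSummary", "transition_matrix", "zone_summary", "level_change"]


@dataclass
class TransitionMatrix:
    """K×K area flows (km²) between the levels of two epochs."""

    from_epoch: str
    to_epoch: str
    areas: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        k = len(self.class_labels)
        if self.areas.shape != (k, k):
            raise ValueError("areas must be K x K")
        if np.any(self.areas < 0):
            raise ValueError("transition areas must be nonnegative")

    @property
    def K(self) -> int:
        return len(self.class_labels)

    def row_totals(self) -> np.ndarray:
        """Level areas at the from-epoch (over cells valid at both)."""
        return self.areas.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        """Level areas at the to-epoch (over cells valid at both)."""
        return self.areas.sum(axis=0)

    def total_area(self) -> float:
        return float(self.areas.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=self.class_labels, columns=self.class_labels)


def transition_matrix(c1: ClassMap, c2: ClassMap) -> TransitionMatrix:
    """Cross-tabulate class membership between two co-registered class maps.

    Only cells valid at both epochs are counted; entry (i, j) is the area
    classed i at the first epoch and j at the second.
    """
    if not c1.grid.same_grid(c2.grid):
        raise ValueError("class maps are not on the same grid")
    if c1.K != c2.K:
        raise ValueError(f"class maps disagree on K: {c1.K} vs {c2.K}")
    both = c1.grid.valid & c2.grid.valid
    a = c1.grid.values[both].astype(int) - 1
    b = c2.grid.values[both].astype(int) - 1
    k = c1.K
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    cell = c1.grid.transform.cell_area_km2()
    return TransitionMatrix(
        from_epoch=c1.epoch,
        to_epoch=c2.epoch,
        areas=counts * cell,
        class_labels=c1.labels,
    )


@dataclass
class ZoneSummary:
    """Per-zone potential statistics for one epoch."""

    zone: str
    epoch: str
    area_km2: float
    mean_inrpi: float  # NaN when the zone is empty
    level_areas_km2: dict[int, float] = field(default_factory=dict)
    level_proportions: dict[int, float] = field(default_factory=dict)
    empty: bool = False


def zone_summary(pm: PotentialMap, cm: ClassMap, zones: ZoneSet) -> list[ZoneSummary]:
    """Area-weighted mean index and per-level area shares for each zone."""
    if zones.template.shape != pm.grid.shape:
        raise ValueError("zones are not co-registered with the potential map")
    cell = pm.grid.transform.cell_area_km2()
    out: list[ZoneSummary] = []
    for name, zmask in zones.zones.items():
        sel = zmask & pm.grid.valid & cm.grid.valid
        n = int(sel.sum())
        if n == 0:
            out.append(
                ZoneSummary(
                    zone=name, epoch=pm.epoch, area_km2=0.0, mean_inrpi=float("nan"),
                    empty=True,
                )
            )
            continue
        vals = pm.grid.values[sel]
        cls = cm.grid.values[sel].astype(int)
        counts = np.bincount(cls, minlength=cm.K + 1)[1:]
        areas = {c + 1: float(counts[c] * cell) for c in range(cm.K)}
        props = {c + 1: float(counts[c] / n) for c in range(cm.K)}
        out.append(
            ZoneSummary(
                zone=name,
                epoch=pm.epoch,
                area_km2=float(n * cell),
                mean_inrpi=float(vals.mean()),
                level_areas_km2=areas,
                level_proportions=props,
            )
        )
    return out


def level_change(areas_t1: dict, areas_t2: dict) -> pd.DataFrame:
    """Signed area change and percent growth rate per level.

    Growth rate is 100·(a2−a1)/a1, NaN (undefined) where a1 = 0.
    """
    if set(areas_t1) != set(areas_t2):
        raise ValueError("level label mismatch between epochs")
    rows = []
    for lvl in areas_t1:
        a1, a2 = float(areas_t1[lvl]), float(areas_t2[lvl])
        rate = float("nan") if a1 == 0 else 100.0 * (a2 - a1) / a1
        rows.append({"level": lvl, "area_t1": a1, "area_t2": a2,
                     "delta_km2": a2 - a1, "growth_rate_pct": rate})
    return pd.DataFrame(rows)
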