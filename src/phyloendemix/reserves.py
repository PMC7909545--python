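"""Protected-area overlap and conservation-gap analysis.

Coverage is the area fraction of each grid cell intersected by the union
of the (non-marine) protected-area polygons — the "<10% coverage" gap
criterion implies fractional area, not centroid containment. A priority
cell whose coverage falls below the threshold is a conservation gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union
from shapely.validation import make_valid

from .canape import CanapeClassification
from .grid import GridSpec
from .hotspots import HotspotSet

__all__ = ["PolygonSet", "cell_coverage", "GapReport", "conservation_gaps"]


@dataclass
class PolygonSet:
    """Planar protected-area polygons with labels and an optional marine
    flag (marine-only designations are excluded from coverage)."""

    polygons: list
    labels: list[str]
    marine: list[bool] | None = None

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.labels):
            raise ValueError("polygons and labels differ in length")
        if self.marine is not None and len(self.marine) != len(self.polygons):
            raise ValueError("marine flags differ in length")

    def terrestrial(self) -> list:
        if self.marine is None:
            return list(self.polygons)
        return [p for p, m in zip(self.polygons, self.marine) if not m]


def cell_coverage(
    grid: GridSpec,
    occupied_cells: Sequence[int],
    polygons: PolygonSet,
) -> pd.Series:
    """Protected area fraction of each cell (exact planar intersection).

    Overlapping polygons are unioned first, so stacked designations never
    double-count. Invalid geometries are repaired; a polygon that stays
    invalid raises with its label.
    """
    geoms = []
    labels = (polygons.labels if polygons.marine is None
              else [l for l, m in zip(polygons.labels, polygons.marine) if not m])
    for poly, label in zip(polygons.terrestrial(), labels):
        if not poly.is_valid:
            poly = make_valid(poly)
            if not poly.is_valid:
                raise ValueError(f"polygon {label!r} invalid after repair")
        geoms.append(poly)
    union = unary_union(geoms) if geoms else None
    area = grid.cell_size ** 2
    fracs = np.zeros(len(occupied_cells))
    if union is not None and not union.is_empty:
        for i, cell in enumerate(occupied_cells):
            cell_box = box(*grid.cell_bounds(int(cell)))
            fracs[i] = cell_box.intersection(union).area / area
    return pd.Series(np.clip(fracs, 0.0, 1.0), index=np.asarray(occupied_cells),
                     name="coverage")


@dataclass
class GapReport:
    """Coverage audit of one priority cell set: which members meet the
    coverage threshold and which are conservation gaps."""

    name: str
    threshold: float
    coverage: pd.Series          # per member cell
    covered: np.ndarray          # cell ids with coverage >= threshold
    gaps: np.ndarray             # cell ids with coverage < threshold
    overlap_pct: float | None    # covered / |set| * 100; None for empty set

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": self.coverage.index,
            "coverage": self.coverage.to_numpy(),
            "gap": [c in set(self.gaps.tolist()) for c in self.coverage.index],
        })


def conservation_gaps(
    cells: HotspotSet | Iterable[int],
    coverage: pd.Series,
    threshold: float = 0.10,
    name: str | None = None,
) -> GapReport:
    """Flag members of a hotspot set (or any cell collection) whose
    protected-area coverage fraction is below ``threshold``."""
    if isinstance(cells, HotspotSet):
        ids = cells.cells
        name = name or f"{cells.metric}_{cells.level}_{cells.tail}"
    elif isinstance(cells, CanapeClassification):
        raise TypeError(
            "pass a single category's cells, e.g. classification.cells_in('paleo')")
    else:
        ids = np.asarray(sorted(cells))
        name = name or "cells"
    if len(ids) == 0:
        return GapReport(name=name, threshold=threshold,
                         coverage=pd.Series(dtype=float),
                         covered=np.array([], dtype=np.int64),
                         gaps=np.array([], dtype=np.int64),
                         overlap_pct=None)
    missing = [c for c in ids if c not in coverage.index]
    if missing:
        raise ValueError(f"coverage undefined for member cells: {missing[:5]}")
    cov = coverage.loc[ids]
    is_gap = cov.to_numpy() < threshold
    covered = np.asarray(ids)[~is_gap]
    gaps = np.asarray(ids)[is_gap]
    return GapReport(
        name=name, threshold=threshold, coverage=cov,
        covered=covered, gaps=gaps,
        overlap_pct=100.0 * len(covered) / len(ids),
    )
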