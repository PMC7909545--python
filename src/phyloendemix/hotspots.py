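"""Percentile hotspots/coldspots, Priority Hotspots and climate-stability
refugia.

Hotspot levels L1/L2/L3 are the top 1%/5%/10% of cells for a metric
(coldspots the corresponding lower tails). Membership uses a nearest-rank
threshold with ties included: the threshold is the k-th most extreme value
(k = max(1, floor(p*n))) and every cell at or beyond it is a member, so an
equally-scoring cell is never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HotspotSet",
    "LEVELS",
    "percentile_cells",
    "priority_hotspots",
    "StabilityRaster",
    "climate_stability",
]

LEVELS = {"L1": 0.01, "L2": 0.05, "L3": 0.10}


@dataclass
class HotspotSet:
    metric: str
    level: str
    tail: str  # "high" | "low"
    threshold: float
    cells: np.ndarray  # member cell ids

    def __contains__(self, cell_id) -> bool:
        return cell_id in set(self.cells.tolist())

    @property
    def cell_set(self) -> set:
        return set(self.cells.tolist())


def percentile_cells(
    values: pd.Series, level: str, tail: str = "high", metric: str = "metric"
) -> HotspotSet:
    """Cells in the top (or bottom) 1/5/10% of a per-cell metric.

    ``values`` is indexed by cell id; NaNs are dropped. All cells tied at
    the threshold are included, so membership can exceed the nominal
    fraction.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {sorted(LEVELS)}")
    if tail not in ("high", "low"):
        raise ValueError("tail must be 'high' or 'low'")
    vals = values.dropna()
    if len(vals) == 0:
        raise ValueError("no finite values")
    p = LEVELS[level]
    n = len(vals)
    k = max(1, int(np.floor(p * n + 1e-9)))
    arr = np.sort(vals.to_numpy())
    if tail == "high":
        threshold = arr[n - k]
        members = vals.index[vals.to_numpy() >= threshold]
    else:
        threshold = arr[k - 1]
        members = vals.index[vals.to_numpy() <= threshold]
    if arr[0] == arr[-1]:
        logger.warning("percentile_cells: all values identical; every cell "
                       "is a member (degenerate)")
    return HotspotSet(
        metric=metric, level=level, tail=tail,
        threshold=float(threshold),
        cells=np.asarray(sorted(members)),
    )


def priority_hotspots(
    cwe_end: pd.Series, pe: pd.Series, level: str
) -> HotspotSet:
    """Priority Hotspots: cells in the high tail of *both* endemic-taxon
    CWE and PE at the same level (the taxonomic x phylogenetic
    intersection used for conservation prioritization)."""
    common = cwe_end.dropna().index.intersection(pe.dropna().index)
    if len(common) == 0:
        raise ValueError("cwe_end and pe share no cells")
    hs_cwe = percentile_cells(cwe_end.loc[common], level, "high", "CWE_END")
    hs_pe = percentile_cells(pe.loc[common], level, "high", "PE")
    members = sorted(hs_cwe.cell_set & hs_pe.cell_set)
    return HotspotSet(
        metric="priority", level=level, tail="high",
        threshold=float("nan"), cells=np.asarray(members),
    )


@dataclass
class StabilityRaster:
    """Per-cell climate stability in [0, 1] (max exactly 1 after rescale)
    with the per-variable components and the refugium cell set."""

    index: pd.Series                   # combined stability
    components: dict                   # variable -> rescaled stability Series
    refugia: HotspotSet


def _stability_one(stack: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Mean |between-slice change| per unit time, inverted and rescaled."""
    diffs = np.abs(np.diff(stack, axis=0))
    dt = np.abs(np.diff(ages)).astype(np.float64)
    if (dt <= 0).any():
        raise ValueError("slice ages must be strictly monotone")
    deviation = (diffs / dt[:, None]).mean(axis=0)
    if np.all(deviation == 0):
        raise ValueError("zero deviation everywhere: constant climate")
    stab = np.full_like(deviation, np.inf)
    nz = deviation > 0
    stab[nz] = 1.0 / deviation[nz]
    if (~nz).any():
        logger.info("climate_stability: %d constant cell(s) capped at the "
                    "finite maximum", int((~nz).sum()))
        stab[~nz] = stab[nz].max()
    return stab / stab.max()


def climate_stability(
    slices: dict[str, np.ndarray],
    ages: np.ndarray,
    cell_ids: np.ndarray,
) -> StabilityRaster:
    """Climate-stability index from per-variable time-slice stacks.

    Parameters
    ----------
    slices
        Mapping variable name -> (n_slices, n_cells) stack, ordered by age.
    ages
        Slice ages (consistent time units); deviations between consecutive
        slices are weighted by the elapsed time.
    cell_ids
        Cell ids aligned with the stacks' columns.

    The per-variable stability is the reciprocal of the time-weighted mean
    absolute between-slice change, rescaled to max 1; the combined index is
    the rescaled product of the variables' stabilities. Refugia are the top
    10% (L3-equivalent) of the combined index.
    """
    ages = np.asarray(ages, dtype=np.float64)
    components = {}
    combined = None
    for var, stack in slices.items():
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 2 or stack.shape[0] < 2:
            raise ValueError(f"{var}: need >= 2 aligned time slices")
        if stack.shape[0] != len(ages):
            raise ValueError(f"{var}: slice count does not match ages")
        stab = _stability_one(stack, ages)
        components[var] = pd.Series(stab, index=cell_ids, name=var)
        combined = stab if combined is None else combined * stab
    if combined is None:
        raise ValueError("no variables supplied")
    combined = combined / combined.max()
    index = pd.Series(combined, index=cell_ids, name="climate_stability")
    refugia = percentile_cells(index, "L3", "high", metric="climate_stability")
    return StabilityRaster(index=index, components=components, refugia=refugia)
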