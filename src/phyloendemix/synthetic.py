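"""Synthetic landscapes with known, recoverable structure.

The generator emulates the inputs of a national-scale endemism study: a
gridded presence/absence flora with a right-skewed range-size
distribution, a subset of narrow-ranged taxa flagged endemic, a dated
phylogeny carrying planted paleo-endemics (range-restricted long pendant
branches) and a planted neo-endemic radiation (a range-restricted clade
of very short branches), spatially autocorrelated environmental surfaces
with known linear effects and spatial error, and protected-area polygons
with controllable coverage of the planted hotspot cells.

Everything derives from one master seed; the ground truth (per-taxon
ranges and cells, planted cell -> expected endemism category, true
regression parameters, intended reserve coverage) is returned as a ledger
so tests can check recovery against it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .grid import CommunityMatrix, GridSpec, OccurrenceRecord, build_matrix
from .reserves import PolygonSet
from .sar import knn_weights

__all__ = [
    "SyntheticScenario",
    "null_scenario",
    "simulate_grid_community",
    "simulate_endemism_tree",
    "simulate_sar_surface",
    "simulate_protected_areas",
    "simulate_paleoclimate_stack",
]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic landscape (defaults: the standard
    recovery scenario — 500 cells, 300 taxa, planted paleo and neo
    blocks)."""

    # grid (5 km cells, planar)
    n_rows: int = 20
    n_cols: int = 25
    cell_size: float = 5000.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    # taxa and ranges
    n_taxa: int = 300
    endemic_fraction: float = 0.50
    range_mu: float = 2.5        # log-cells, background taxa
    range_sigma: float = 0.8
    background_min_range: int = 10  # keeps planted narrow-endemics the top CWE signal
    placement: str = "dye"       # "dye" (contiguous patches) | "scatter"

    # planted paleo-endemism block
    n_paleo_cells: int = 10
    n_paleo_taxa: int = 10
    paleo_length_multiplier: float = 10.0

    # planted neo-endemism block
    n_neo_cells: int = 10
    n_neo_taxa: int = 25
    neo_depth_fraction: float = 0.08

    planted_range_min: int = 2
    planted_range_max: int = 4

    # environmental surfaces and SAR truth
    n_predictors: int = 2
    field_range: float = 3.0     # Gaussian-field smoothing radius, in cells
    sar_beta: tuple = (1.0, -0.5)
    sar_lambda: float = 0.6
    sar_sigma: float = 1.0
    sar_k: int = 4

    # protected areas
    pa_coverage_fraction: float = 0.8
    pa_decoy_count: int = 15
    pa_cell_cover: float = 0.30  # covered fraction within each covered cell

    seed: int = 20210120

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.origin_x, self.origin_y, self.cell_size,
                        self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def __post_init__(self) -> None:
        n_planted = self.n_paleo_taxa + self.n_neo_taxa
        if n_planted > int(round(self.endemic_fraction * self.n_taxa)):
            raise ValueError("planted taxa exceed the endemic taxon count")
        if self.n_paleo_cells + self.n_neo_cells > self.n_cells:
            raise ValueError("planted cell blocks exceed the grid")


def null_scenario(seed: int = 0) -> SyntheticScenario:
    """No-signal calibration landscape: 200 cells, 200 taxa of which 150
    endemic, scattered (null-distributed) placement, nothing planted."""
    return SyntheticScenario(
        n_rows=8, n_cols=25, n_taxa=200, endemic_fraction=0.75,
        range_mu=2.0, range_sigma=0.8, background_min_range=1,
        placement="scatter",
        n_paleo_cells=0, n_paleo_taxa=0, n_neo_cells=0, n_neo_taxa=0,
        seed=seed,
    )


# -- community --------------------------------------------------------------

def _block_cells(rng: np.random.Generator, grid: GridSpec, n_cells: int,
                 forbidden: set[int]) -> list[int]:
    """A contiguous rectangular block of cells avoiding `forbidden`."""
    if n_cells == 0:
        return []
    h = 2 if n_cells >= 4 else 1
    w = int(np.ceil(n_cells / h))
    for _ in range(1000):
        r0 = int(rng.integers(0, grid.n_rows - h + 1))
        c0 = int(rng.integers(0, grid.n_cols - w + 1))
        cells = [(r0 + dr) * grid.n_cols + (c0 + dc)
                 for dr in range(h) for dc in range(w)][:n_cells]
        if not (set(cells) & forbidden):
            return cells
    raise RuntimeError("could not place a planted block")


def _spreading_dye(rng: np.random.Generator, grid: GridSpec, seed_cell: int,
                   size: int, allowed: set[int] | None = None) -> list[int]:
    """Grow a 4-connected patch of `size` cells from a seed cell."""
    def neighbours(cell: int):
        r, c = divmod(cell, grid.n_cols)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                yield rr * grid.n_cols + cc

    patch = {seed_cell}
    frontier = {n for n in neighbours(seed_cell)
                if allowed is None or n in allowed}
    while len(patch) < size and frontier:
        nxt = int(rng.choice(sorted(frontier)))
        patch.add(nxt)
        frontier.discard(nxt)
        for n in neighbours(nxt):
            if n not in patch and (allowed is None or n in allowed):
                frontier.add(n)
    return sorted(patch)


def simulate_grid_community(
    sc: SyntheticScenario,
) -> tuple[CommunityMatrix, dict]:
    """Generate the community matrix and its ground-truth ledger.

    Background taxa draw log-normal range sizes (rounded, clipped to
    [background_min_range, n_cells]) realized as spreading-dye patches
    (or uniform scatter); planted paleo/neo taxa draw small ranges
    realized inside their blocks, with block cells used round-robin as
    dye seeds so every planted cell holds at least one planted taxon.
    Endemics are the lowest-range quantile of taxa.
    """
    ss = np.random.SeedSequence([sc.seed, 1])
    rng = np.random.default_rng(ss)
    grid = sc.grid

    paleo_cells = _block_cells(rng, grid, sc.n_paleo_cells, set())
    neo_cells = _block_cells(rng, grid, sc.n_neo_cells, set(paleo_cells))

    n_background = sc.n_taxa - sc.n_paleo_taxa - sc.n_neo_taxa
    width = len(str(sc.n_taxa - 1))
    taxon_ids = [f"Genus{i % 40:02d}_sp{i:0{width}d}" for i in range(sc.n_taxa)]
    planted_kind = (["paleo"] * sc.n_paleo_taxa + ["neo"] * sc.n_neo_taxa
                    + ["none"] * n_background)

    cells_of: dict[str, list[int]] = {}
    for i, (tid, kind) in enumerate(zip(taxon_ids, planted_kind)):
        if kind != "none":
            block = paleo_cells if kind == "paleo" else neo_cells
            size = int(rng.integers(sc.planted_range_min,
                                    sc.planted_range_max + 1))
            k = i if kind == "paleo" else i - sc.n_paleo_taxa
            seed_cell = block[k % len(block)]
            cells_of[tid] = _spreading_dye(rng, grid, seed_cell,
                                           min(size, len(block)), set(block))
        else:
            size = int(round(float(rng.lognormal(sc.range_mu, sc.range_sigma))))
            size = int(np.clip(size, sc.background_min_range, sc.n_cells))
            if sc.placement == "scatter":
                cells_of[tid] = sorted(
                    rng.choice(sc.n_cells, size=size, replace=False).tolist())
            else:
                seed_cell = int(rng.integers(0, sc.n_cells))
                cells_of[tid] = _spreading_dye(rng, grid, seed_cell, size)

    realized = np.array([len(cells_of[t]) for t in taxon_ids])
    n_endemic = int(round(sc.endemic_fraction * sc.n_taxa))
    order = np.lexsort((np.arange(sc.n_taxa), realized))  # range, then index
    endemic_ids = {taxon_ids[i] for i in order[:n_endemic]}

    records = [
        OccurrenceRecord(taxon_id=t, cell_id=c, endemic=(t in endemic_ids))
        for t in taxon_ids for c in cells_of[t]
    ]
    matrix = build_matrix(records, grid)

    planted_hotspot_cells = sorted(set(paleo_cells) | set(neo_cells))
    ledger = {
        "taxa": pd.DataFrame({
            "taxon": taxon_ids,
            "planted": planted_kind,
            "range": realized,
            "endemic": [t in endemic_ids for t in taxon_ids],
            "cells": [cells_of[t] for t in taxon_ids],
        }),
        "paleo_cells": sorted(paleo_cells),
        "neo_cells": sorted(neo_cells),
        "planted_hotspot_cells": planted_hotspot_cells,
        "expected_category": {
            **{c: "paleo" for c in paleo_cells},
            **{c: "neo" for c in neo_cells},
        },
    }
    return matrix, ledger


# -- phylogeny --------------------------------------------------------------

def _yule_tree(n_tips: int, pyrng: random.Random) -> dendropy.Tree:
    from dendropy.model import birthdeath
    return birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=pyrng)


def _tip_depths(tree: dendropy.Tree) -> dict:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf: leaf.root_distance for leaf in tree.leaf_node_iter()}


def simulate_endemism_tree(
    sc: SyntheticScenario, matrix: CommunityMatrix
) -> tuple[dendropy.Tree, dict]:
    """Yule backbone over all taxa, with the planted paleo taxa turned
    into long isolated pendant branches (multiplier x the median pendant
    length) and the planted neo taxa attached as a shallow radiation (a
    clade whose crown sits at `neo_depth_fraction` of tree height)."""
    taxon_ids = list(matrix.taxon_ids)
    # planted identity comes from position: regenerate the same id layout
    width = len(str(sc.n_taxa - 1))
    ids_in_order = [f"Genus{i % 40:02d}_sp{i:0{width}d}" for i in range(sc.n_taxa)]
    paleo_ids = ids_in_order[:sc.n_paleo_taxa]
    neo_ids = ids_in_order[sc.n_paleo_taxa:sc.n_paleo_taxa + sc.n_neo_taxa]
    backbone_ids = ids_in_order[sc.n_paleo_taxa + sc.n_neo_taxa:]

    ss = np.random.SeedSequence([sc.seed, 2])
    rng = np.random.default_rng(ss)
    pyrng = random.Random(int(rng.integers(0, 2**31 - 1)))

    n_backbone = len(backbone_ids) + len(paleo_ids) + (1 if neo_ids else 0)
    tree = _yule_tree(n_backbone, pyrng)
    leaves = list(tree.leaf_node_iter())
    perm = rng.permutation(len(leaves))
    labels = paleo_ids + (["__neo_clade__"] if neo_ids else []) + backbone_ids
    for leaf, j in zip(leaves, perm):
        leaf.taxon.label = labels[j]

    pendants = np.array([lf.edge.length for lf in tree.leaf_node_iter()])
    median_pendant = float(np.median(pendants))

    # paleo: long isolated pendant branches
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in paleo_ids:
            leaf.edge.length = sc.paleo_length_multiplier * median_pendant

    # neo: replace the placeholder tip with a shallow radiation
    if neo_ids:
        depths = _tip_depths(tree)
        height = max(d for d in depths.values())
        placeholder = next(lf for lf in tree.leaf_node_iter()
                           if lf.taxon.label == "__neo_clade__")
        h = sc.neo_depth_fraction * height
        stem_len = placeholder.edge.length
        if h >= 0.9 * stem_len:
            h = 0.5 * stem_len
        sub = _yule_tree(len(neo_ids), pyrng)
        sub_height = max(_tip_depths(sub).values())
        scale = h / sub_height
        for edge in sub.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
        for tip, label in zip(sub.leaf_node_iter(), neo_ids):
            tip.taxon.label = label
        placeholder.taxon = None
        placeholder.edge.length = stem_len - h
        for child in list(sub.seed_node.child_nodes()):
            sub.seed_node.remove_child(child)
            placeholder.add_child(child)

    # rebuild the taxon namespace from the final labels
    newick = tree.as_string(schema="newick", unquoted_underscores=True)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(taxon_ids) - tip_labels
    if missing:
        raise RuntimeError(f"tree is missing taxa: {sorted(missing)[:5]}")

    ledger = {
        "paleo_taxa": paleo_ids,
        "neo_taxa": neo_ids,
        "median_pendant": median_pendant,
    }
    return tree, ledger


# -- environment + SAR response ---------------------------------------------

def _gaussian_field(rng: np.random.Generator, n_rows: int, n_cols: int,
                    smooth: float) -> np.ndarray:
    z = rng.standard_normal((n_rows, n_cols))
    z = ndimage.gaussian_filter(z, sigma=smooth, mode="wrap")
    z = (z - z.mean()) / z.std()
    return z.ravel()


def simulate_sar_surface(
    sc: SyntheticScenario, grid: GridSpec | None = None
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Spatially autocorrelated predictors plus a response with known
    linear effects and spatial error: y = X beta + u, (I - lambda W) u =
    eps, on row-standardized symmetrized k-NN weights."""
    grid = grid or sc.grid
    ss = np.random.SeedSequence([sc.seed, 3])
    rng = np.random.default_rng(ss)
    n = grid.n_cells
    beta = np.asarray(sc.sar_beta, dtype=np.float64)
    if len(beta) != sc.n_predictors:
        raise ValueError("sar_beta length must equal n_predictors")
    X = pd.DataFrame({
        f"env{j + 1}": _gaussian_field(rng, grid.n_rows, grid.n_cols,
                                       sc.field_range)
        for j in range(sc.n_predictors)
    })
    W = knn_weights(grid.centroids(), sc.sar_k)
    eig = np.real(np.linalg.eigvals(W))
    if not (1.0 / eig.min() < sc.sar_lambda < 1.0 / eig.max()):
        raise ValueError("sar_lambda outside the feasible interval")
    eps = sc.sar_sigma * rng.standard_normal(n)
    u = np.linalg.solve(np.eye(n) - sc.sar_lambda * W, eps)
    y = X.to_numpy() @ beta + u
    truth = {"beta": beta.tolist(), "lambda": sc.sar_lambda,
             "sigma": sc.sar_sigma, "k": sc.sar_k}
    return y, X, truth


def simulate_paleoclimate_stack(
    sc: SyntheticScenario,
    n_slices: int = 4,
    stable_cells: list[int] | None = None,
    grid: GridSpec | None = None,
) -> tuple[dict, np.ndarray, list[int]]:
    """Time-slice stacks for temperature and precipitation with a planted
    low-variability patch (the intended climate refugium)."""
    grid = grid or sc.grid
    ss = np.random.SeedSequence([sc.seed, 5])
    rng = np.random.default_rng(ss)
    n = grid.n_cells
    if stable_cells is None:
        stable_cells = _block_cells(rng, grid, max(4, n // 20), set())
    ages = np.linspace(0.0, 4.0, n_slices)  # e.g. My before present
    amp = rng.uniform(0.8, 1.2, size=n)
    amp[np.asarray(stable_cells)] = 0.02  # nearly constant through time
    slices = {}
    for var, base in (("temperature", 15.0), ("precipitation", 700.0)):
        stack = np.empty((n_slices, n))
        level = base + rng.standard_normal(n)
        for t in range(n_slices):
            stack[t] = level + amp * rng.standard_normal(n)
        slices[var] = stack
    return slices, ages, sorted(stable_cells)


def make_collinear_predictors(
    n_core: int = 13,
    n_derived: int = 34,
    n_samples: int = 500,
    n_groups: int = 3,
    alpha2: float = 0.95,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """A predictor table with a known independent core plus redundant
    derived columns, built so the Spearman/VIF screen recovers exactly
    the core.

    Each derived column is a dense +-1/sqrt(n_core) combination of *all*
    core columns (multiple correlation sqrt(alpha2) ~ 0.97 with the core
    set) plus independent noise, using one of ``n_groups`` sign patterns.
    Same-pattern derived columns correlate pairwise at ~alpha2 and are
    whittled down by the pairwise-correlation phase (derived against
    derived only — no derived column ever exceeds |rho| 0.7 with any
    single core); the per-pattern survivors carry VIF ~1/(1-alpha2) >= 10
    and fall to the VIF phase, while each core's VIF stays well under 10.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    core = rng.standard_normal((n_samples, n_core))
    core_names = [f"core{j:02d}" for j in range(n_core)]

    signs = []
    while len(signs) < n_groups:
        s = rng.choice([-1.0, 1.0], size=n_core)
        if all(abs(s @ t) <= 3 for t in signs):
            signs.append(s)

    a = np.sqrt(alpha2)
    b = np.sqrt(1.0 - alpha2)
    data = {name: core[:, j] for j, name in enumerate(core_names)}
    for mcol in range(n_derived):
        s = signs[mcol % n_groups]
        combo = (core @ s) / np.sqrt(n_core)
        data[f"derived{mcol:02d}"] = a * combo + b * rng.standard_normal(n_samples)
    return pd.DataFrame(data), core_names


# -- protected areas --------------------------------------------------------

def simulate_protected_areas(
    grid: GridSpec,
    target_cells: list[int],
    coverage_fraction: float,
    decoy_count: int = 10,
    seed: int = 0,
    cell_cover: float = 0.30,
) -> tuple[PolygonSet, dict]:
    """Rectangular reserve polygons covering `coverage_fraction` of the
    target cells at `cell_cover` area fraction each (comfortably above
    the 10% gap threshold), plus decoy polygons elsewhere."""
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must lie in [0, 1]")
    for c in target_cells:
        if not 0 <= c < grid.n_cells:
            raise ValueError(f"target cell {c} outside grid")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    targets = np.asarray(sorted(target_cells))
    n_cov = int(round(coverage_fraction * len(targets)))
    covered = sorted(rng.permutation(targets)[:n_cov].tolist())

    polys, labels = [], []
    for i, cell in enumerate(covered):
        x0, y0, x1, y1 = grid.cell_bounds(cell)
        polys.append(box(x0, y0, x1, y0 + cell_cover * (y1 - y0)))
        labels.append(f"sac_target_{i:03d}")
    target_set = set(targets.tolist())
    other = [c for c in range(grid.n_cells) if c not in target_set]
    decoys = rng.choice(len(other), size=min(decoy_count, len(other)),
                        replace=False)
    for i, oi in enumerate(sorted(decoys.tolist())):
        x0, y0, x1, y1 = grid.cell_bounds(other[oi])
        polys.append(box(x0, y0, x1, y0 + cell_cover * (y1 - y0)))
        labels.append(f"sac_decoy_{i:03d}")

    pset = PolygonSet(polygons=polys, labels=labels,
                      marine=[False] * len(polys))
    ledger = {"covered_targets": covered,
              "gap_targets": sorted(target_set - set(covered))}
    return pset, ledger
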