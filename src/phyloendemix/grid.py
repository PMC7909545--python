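"""Gridded community data: grid geometry, occurrence records and the
cells x taxa presence/absence matrix that every downstream metric consumes.

All geometry is planar (projected coordinates in metres or any consistent
unit). Geographic lon/lat input must be projected before use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "OccurrenceRecord",
    "CommunityMatrix",
    "assign_cells",
    "build_matrix",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid; cell ids are 0-based, row-major from the
    lower-left corner (cell 0 spans [origin_x, origin_x + cell_size) x
    [origin_y, origin_y + cell_size)).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local-planar"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        return divmod(int(cell_id), self.n_cols)

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of a cell."""
        row, col = self.rowcol(cell_id)
        x0 = self.origin_x + col * self.cell_size
        y0 = self.origin_y + row * self.cell_size
        return (x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def centroids(self, cell_ids: Sequence[int] | None = None) -> np.ndarray:
        """(n, 2) array of cell-centre coordinates."""
        ids = np.arange(self.n_cells) if cell_ids is None else np.asarray(cell_ids)
        rows, cols = np.divmod(ids, self.n_cols)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (rows + 0.5) * self.cell_size
        return np.column_stack([x, y])


@dataclass
class OccurrenceRecord:
    """One occurrence: a taxon either located by planar (x, y) or already
    assigned to a grid cell."""

    taxon_id: str
    x: float | None = None
    y: float | None = None
    cell_id: int | None = None
    endemic: bool = False

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")
        has_xy = self.x is not None and self.y is not None
        if has_xy == (self.cell_id is not None):
            raise ValueError(
                f"record for {self.taxon_id!r}: exactly one of (x, y) or "
                "cell_id must be set"
            )


def assign_cells(
    records: Iterable[OccurrenceRecord], grid: GridSpec
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Assign a grid cell to each coordinate-bearing record.

    Points on an interior upper/right cell boundary belong to the next cell;
    points on the outermost upper/right grid boundary are clamped inward.
    Records outside the grid bounding box are returned in a rejects list,
    never silently dropped. Records that already carry a cell_id pass
    through unchanged (the operation is idempotent).

    Returns
    -------
    (assigned, rejects)
    """
    assigned: list[OccurrenceRecord] = []
    rejects: list[OccurrenceRecord] = []
    xmax = grid.origin_x + grid.n_cols * grid.cell_size
    ymax = grid.origin_y + grid.n_rows * grid.cell_size
    for rec in records:
        if rec.cell_id is not None:
            if not 0 <= rec.cell_id < grid.n_cells:
                rejects.append(rec)
            else:
                assigned.append(rec)
            continue
        if not (grid.origin_x <= rec.x <= xmax and grid.origin_y <= rec.y <= ymax):
            rejects.append(rec)
            continue
        col = int(np.floor((rec.x - grid.origin_x) / grid.cell_size))
        row = int(np.floor((rec.y - grid.origin_y) / grid.cell_size))
        col = min(col, grid.n_cols - 1)  # clamp outermost boundary inward
        row = min(row, grid.n_rows - 1)
        assigned.append(replace(rec, x=None, y=None, cell_id=row * grid.n_cols + col))
    if rejects:
        logger.warning("assign_cells: %d record(s) outside the grid", len(rejects))
    return assigned, rejects


@dataclass
class CommunityMatrix:
    """Cells x taxa presence/absence with per-taxon endemic flags.

    Rows are the *occupied* cells only (cells with zero taxa are dropped
    from the row index but remain recoverable from the GridSpec). Columns
    follow ``taxon_ids`` and align with ``endemic_mask``.
    """

    presence: np.ndarray  # (n_cells, n_taxa) uint8 in {0,1}
    cell_ids: np.ndarray  # (n_cells,) int
    taxon_ids: list[str]
    endemic_mask: np.ndarray  # (n_taxa,) bool
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.presence = np.ascontiguousarray(self.presence, dtype=np.uint8)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.endemic_mask = np.asarray(self.endemic_mask, dtype=bool)
        n_cells, n_taxa = self.presence.shape
        if len(self.cell_ids) != n_cells or len(self.taxon_ids) != n_taxa:
            raise ValueError("index lengths do not match presence shape")
        if len(self.endemic_mask) != n_taxa:
            raise ValueError("endemic_mask length does not match taxa")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")

    # -- derived quantities -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.presence.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.presence.shape[1]

    @property
    def sr(self) -> np.ndarray:
        """Per-cell richness over all taxa (row sums)."""
        return self.presence.sum(axis=1).astype(np.int64)

    @property
    def er(self) -> np.ndarray:
        """Per-cell richness over endemic taxa only."""
        return self.presence[:, self.endemic_mask].sum(axis=1).astype(np.int64)

    @property
    def ranges(self) -> np.ndarray:
        """Per-taxon range size in cells (column sums)."""
        return self.presence.sum(axis=0).astype(np.int64)

    # -- transforms ---------------------------------------------------------
    def subset_taxa(self, mask: np.ndarray, drop_empty_cells: bool = True) -> "CommunityMatrix":
        """Restrict to a taxon subset; optionally drop cells left empty."""
        mask = np.asarray(mask, dtype=bool)
        pres = self.presence[:, mask]
        ids = self.cell_ids
        if drop_empty_cells:
            keep = pres.sum(axis=1) > 0
            pres = pres[keep]
            ids = ids[keep]
        return CommunityMatrix(
            presence=pres.copy(),
            cell_ids=ids.copy(),
            taxon_ids=[t for t, m in zip(self.taxon_ids, mask) if m],
            endemic_mask=self.endemic_mask[mask].copy(),
            grid=self.grid,
        )

    def endemic_submatrix(self) -> "CommunityMatrix":
        """The endemic-taxon community on cells holding >= 1 endemic."""
        return self.subset_taxa(self.endemic_mask)


def build_matrix(
    records: Iterable[OccurrenceRecord], grid: GridSpec | None = None
) -> CommunityMatrix:
    """Collapse cell-assigned occurrence records into a CommunityMatrix.

    Duplicate (taxon, cell) pairs collapse silently (their count is logged);
    conflicting endemic flags for one taxon raise; empty cells never enter
    the row index.
    """
    records = list(records)
    if not records:
        raise ValueError("no occurrence records supplied")
    endemic_by_taxon: dict[str, bool] = {}
    pairs: set[tuple[str, int]] = set()
    n_dupes = 0
    for rec in records:
        if rec.cell_id is None:
            raise ValueError(f"record for {rec.taxon_id!r} lacks a cell_id")
        prev = endemic_by_taxon.get(rec.taxon_id)
        if prev is None:
            endemic_by_taxon[rec.taxon_id] = bool(rec.endemic)
        elif prev != bool(rec.endemic):
            raise ValueError(
                f"conflicting endemic flags for taxon {rec.taxon_id!r}"
            )
        key = (rec.taxon_id, int(rec.cell_id))
        if key in pairs:
            n_dupes += 1
        else:
            pairs.add(key)
    if n_dupes:
        logger.info("build_matrix: collapsed %d duplicate (taxon, cell) pairs", n_dupes)

    taxon_ids = sorted(endemic_by_taxon)
    cells = sorted({c for _, c in pairs})
    t_index = {t: j for j, t in enumerate(taxon_ids)}
    c_index = {c: i for i, c in enumerate(cells)}
    presence = np.zeros((len(cells), len(taxon_ids)), dtype=np.uint8)
    for taxon, cell in pairs:
        presence[c_index[cell], t_index[taxon]] = 1
    return CommunityMatrix(
        presence=presence,
        cell_ids=np.array(cells, dtype=np.int64),
        taxon_ids=taxon_ids,
        endemic_mask=np.array([endemic_by_taxon[t] for t in taxon_ids], dtype=bool),
        grid=grid,
    )
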