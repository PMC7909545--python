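"""File I/O for the pipeline's plain-text interchange formats.

Occurrences and metric tables are delimited text, trees are Newick
(via dendropy), polygons are GeoJSON (via shapely), and per-cell raster
values are ``cell,value`` text. All geometry is planar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import CommunityMatrix, GridSpec, OccurrenceRecord

__all__ = [
    "read_occurrences",
    "write_occurrences",
    "read_tree",
    "write_tree",
    "write_matrix",
    "read_matrix",
    "read_polygons",
    "write_polygons",
    "read_cell_values",
    "write_cell_values",
]


# -- occurrences ------------------------------------------------------------

def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read `taxon,x,y,endemic` or `taxon,cell,endemic` delimited text."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    recs: list[OccurrenceRecord] = []
    if {"taxon", "x", "y"} <= cols:
        for row in df.itertuples(index=False):
            recs.append(
                OccurrenceRecord(
                    taxon_id=str(row.taxon), x=float(row.x), y=float(row.y),
                    endemic=bool(row.endemic),
                )
            )
    elif {"taxon", "cell"} <= cols:
        for row in df.itertuples(index=False):
            recs.append(
                OccurrenceRecord(
                    taxon_id=str(row.taxon), cell_id=int(row.cell),
                    endemic=bool(row.endemic),
                )
            )
    else:
        raise ValueError(
            f"{path}: expected header taxon,x,y,endemic or taxon,cell,endemic"
        )
    return recs


def write_occurrences(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    if all(r.cell_id is not None for r in records):
        df = pd.DataFrame(
            {"taxon": [r.taxon_id for r in records],
             "cell": [r.cell_id for r in records],
             "endemic": [int(r.endemic) for r in records]}
        )
    else:
        df = pd.DataFrame(
            {"taxon": [r.taxon_id for r in records],
             "x": [r.x for r in records],
             "y": [r.y for r in records],
             "endemic": [int(r.endemic) for r in records]}
        )
    df.to_csv(path, index=False)


# -- trees ------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# -- community matrix (sparse triplet + taxa sidecar + grid json) -----------

def write_matrix(matrix: CommunityMatrix, outdir: str | Path) -> None:
    """Write sparse triplets `cell,taxon`, a taxa sidecar
    `taxon,endemic,range`, and the grid spec (if any) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ci, ti = np.nonzero(matrix.presence)
    pd.DataFrame(
        {"cell": matrix.cell_ids[ci],
         "taxon": [matrix.taxon_ids[j] for j in ti]}
    ).to_csv(outdir / "matrix.csv", index=False)
    pd.DataFrame(
        {"taxon": matrix.taxon_ids,
         "endemic": matrix.endemic_mask.astype(int),
         "range": matrix.ranges}
    ).to_csv(outdir / "taxa.csv", index=False)
    if matrix.grid is not None:
        g = matrix.grid
        (outdir / "grid.json").write_text(json.dumps({
            "origin_x": g.origin_x, "origin_y": g.origin_y,
            "cell_size": g.cell_size, "n_rows": g.n_rows,
            "n_cols": g.n_cols, "crs_label": g.crs_label,
        }, indent=1))


def read_matrix(indir: str | Path) -> CommunityMatrix:
    indir = Path(indir)
    trip = pd.read_csv(indir / "matrix.csv")
    taxa = pd.read_csv(indir / "taxa.csv")
    grid = None
    if (indir / "grid.json").exists():
        grid = GridSpec(**json.loads((indir / "grid.json").read_text()))
    taxon_ids = [str(t) for t in taxa["taxon"]]
    t_index = {t: j for j, t in enumerate(taxon_ids)}
    cells = np.array(sorted(trip["cell"].unique()), dtype=np.int64)
    c_index = {c: i for i, c in enumerate(cells)}
    presence = np.zeros((len(cells), len(taxon_ids)), dtype=np.uint8)
    for cell, taxon in zip(trip["cell"], trip["taxon"]):
        presence[c_index[cell], t_index[str(taxon)]] = 1
    return CommunityMatrix(
        presence=presence, cell_ids=cells, taxon_ids=taxon_ids,
        endemic_mask=taxa["endemic"].to_numpy(dtype=bool), grid=grid,
    )


# -- polygons (GeoJSON) -----------------------------------------------------

def read_polygons(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    """Read a GeoJSON FeatureCollection; returns (geometries, properties)."""
    gj = json.loads(Path(path).read_text())
    geoms, props = [], []
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    for feat in feats:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props


def write_polygons(
    geoms: Sequence[BaseGeometry], path: str | Path,
    properties: Sequence[dict] | None = None,
) -> None:
    feats = []
    for i, g in enumerate(geoms):
        feats.append({
            "type": "Feature",
            "geometry": mapping(g),
            "properties": (properties[i] if properties is not None else {}),
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


# -- per-cell raster values -------------------------------------------------

def read_cell_values(path: str | Path, value_col: str | None = None) -> pd.Series:
    """Read `cell,value` text into a Series indexed by cell id."""
    df = pd.read_csv(path)
    col = value_col or [c for c in df.columns if c != "cell"][0]
    return pd.Series(df[col].to_numpy(), index=df["cell"].to_numpy(), name=col)


def write_cell_values(values: pd.Series, path: str | Path, name: str = "value") -> None:
    pd.DataFrame({"cell": values.index, name: values.to_numpy()}).to_csv(
        path, index=False)
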