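"""One-command orchestration of the full analysis.

Stages run in dependency order — community, tree, metrics, nulls, CANAPE,
hotspots, priority hotspots, reserve gaps, SAR — each writing plain-text
outputs into the run directory; a manifest records the configuration and
a SHA-256 hash of every file, so two runs of one config are comparable by
hash equality. All randomness flows from the single seed through named
substreams, making each stage independently replayable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pxio
from .canape import classify_cells
from .grafting import GraftEntry, graft_missing_taxa
from .grid import assign_cells, build_matrix, GridSpec
from .hotspots import LEVELS, percentile_cells, priority_hotspots
from .metrics import cell_metrics
from .randomization import null_pvalues
from .reserves import PolygonSet, cell_coverage, conservation_gaps
from .sar import select_sar, standardize
from .synthetic import (
    SyntheticScenario,
    simulate_endemism_tree,
    simulate_grid_community,
    simulate_protected_areas,
    simulate_sar_surface,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = ("community", "tree", "metrics", "nulls", "canape", "hotspots",
          "priority", "gaps", "sar")


@dataclass
class RunConfig:
    outdir: str = "phyloendemix_run"
    seed: int = 0
    reps: int = 199
    null: str = "curveball"
    alpha_primary: float = 0.05
    alpha_rpe_tail: float = 0.025
    alpha_super: float = 0.01
    levels: tuple = ("L1", "L2", "L3")
    gap_threshold: float = 0.10
    sar_k_candidates: tuple = (1, 2, 3, 4, 5, 6, 7, 8)

    # synthetic mode (default): scenario overrides merged onto defaults
    scenario: dict = field(default_factory=dict)

    # file mode: all four paths must be given to bypass the generator
    occurrences: str | None = None
    grid: dict | None = None          # origin_x, origin_y, cell_size, n_rows, n_cols
    tree: str | None = None
    graft_list: str | None = None
    reserves: str | None = None       # GeoJSON
    predictors: str | None = None     # cell,<name>,... text

    def validate(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for lvl in self.levels:
            if lvl not in LEVELS:
                raise ValueError(f"unknown hotspot level {lvl!r}")
        file_mode = self.occurrences is not None
        if file_mode and self.grid is None:
            raise ValueError("file mode needs a grid specification")

    @property
    def file_mode(self) -> bool:
        return self.occurrences is not None


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and return the output directory.

    A failing stage leaves the completed stages' outputs in place, writes
    ``error_manifest.json`` naming the stage and cause, and re-raises.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "setup"
    try:
        # -- community ----------------------------------------------------
        stage = "community"
        ledger = None
        if cfg.file_mode:
            grid = GridSpec(**cfg.grid)
            records = pxio.read_occurrences(cfg.occurrences)
            assigned, rejects = assign_cells(records, grid)
            if rejects:
                logger.warning("%d occurrence record(s) rejected", len(rejects))
            matrix = build_matrix(assigned, grid)
            sc = None
        else:
            sc = SyntheticScenario(**{"seed": seed, **cfg.scenario})
            matrix, ledger = simulate_grid_community(sc)
            grid = sc.grid
        pxio.write_matrix(matrix, out / "matrix")
        for f in ("matrix.csv", "taxa.csv", "grid.json"):
            if (out / "matrix" / f).exists():
                written.append(out / "matrix" / f)
        if ledger is not None:
            emit("ground_truth.json", lambda p: p.write_text(json.dumps({
                "paleo_cells": ledger["paleo_cells"],
                "neo_cells": ledger["neo_cells"],
                "planted_hotspot_cells": ledger["planted_hotspot_cells"],
            }, indent=1)))

        # -- tree ---------------------------------------------------------
        stage = "tree"
        if cfg.file_mode:
            tree = pxio.read_tree(cfg.tree)
            if cfg.graft_list:
                gl = pd.read_csv(cfg.graft_list)
                entries = [
                    GraftEntry(
                        taxon_id=str(r.taxon),
                        genus=(str(r.genus) if "genus" in gl.columns
                               and pd.notna(r.genus) else None),
                        parent_species=(str(r.parent_species)
                                        if "parent_species" in gl.columns
                                        and pd.notna(r.parent_species) else None),
                    )
                    for r in gl.itertuples(index=False)
                ]
                tree = graft_missing_taxa(tree, entries, seed=seed)
        else:
            tree, _tree_ledger = simulate_endemism_tree(sc, matrix)
        emit("tree.nwk", lambda p: pxio.write_tree(tree, p))

        # -- metrics --------------------------------------------------------
        stage = "metrics"
        mtab = cell_metrics(matrix, tree)
        emit("metrics.csv", lambda p: mtab.to_csv(p, index=False))

        # -- nulls ----------------------------------------------------------
        stage = "nulls"
        end = matrix.endemic_submatrix()
        null = null_pvalues(end, tree, reps=cfg.reps,
                            seed=seed + 1, null=cfg.null)
        emit("nulls.csv", lambda p: null.to_frame().to_csv(p, index=False))

        # -- canape ---------------------------------------------------------
        stage = "canape"
        cls = classify_cells(null, cfg.alpha_primary, cfg.alpha_rpe_tail,
                             cfg.alpha_super)
        emit("canape.csv", lambda p: cls.to_frame().to_csv(p, index=False))
        emit("canape_counts.json", lambda p: p.write_text(
            json.dumps(cls.counts().to_dict(), indent=1)))

        # -- hotspots ---------------------------------------------------------
        stage = "hotspots"
        m = mtab.set_index("cell")
        rows = []
        for metric, tails in (("SR", ("high",)), ("ER", ("high",)),
                              ("CWE_NAT", ("high",)),
                              ("CWE_END", ("high", "low"))):
            series = m[metric].dropna()
            for level in cfg.levels:
                for tail in tails:
                    hs = percentile_cells(series, level, tail, metric=metric)
                    for c in hs.cells:
                        rows.append({"cell": int(c), "metric": metric,
                                     "level": level, "tail": tail,
                                     "threshold": hs.threshold})
        hdf = pd.DataFrame(rows)
        emit("hotspots.csv", lambda p: hdf.to_csv(p, index=False))

        # -- priority hotspots ------------------------------------------------
        stage = "priority"
        prios = {lvl: priority_hotspots(m["CWE_END"], m["PE_obs"], lvl)
                 for lvl in cfg.levels}
        pdf = pd.DataFrame(
            [{"cell": int(c), "level": lvl}
             for lvl, hs in prios.items() for c in hs.cells])
        emit("priority.csv", lambda p: pdf.to_csv(p, index=False))

        # -- reserve gaps -----------------------------------------------------
        stage = "gaps"
        if cfg.file_mode and cfg.reserves:
            geoms, props = pxio.read_polygons(cfg.reserves)
            pset = PolygonSet(
                polygons=geoms,
                labels=[str(pr.get("label", i)) for i, pr in enumerate(props)],
                marine=[bool(pr.get("marine", False)) for pr in props],
            )
        elif not cfg.file_mode:
            widest = cfg.levels[-1]
            targets = prios[widest].cells.tolist()
            pset, _pa_ledger = simulate_protected_areas(
                grid, targets, sc.pa_coverage_fraction, sc.pa_decoy_count,
                seed=seed + 2, cell_cover=sc.pa_cell_cover)
            pxio.write_polygons(pset.polygons, out / "sac.geojson",
                                [{"label": l, "marine": False}
                                 for l in pset.labels])
            written.append(out / "sac.geojson")
        else:
            pset = None
        if pset is not None and len(pset.polygons) > 0:
            coverage = cell_coverage(grid, matrix.cell_ids.tolist(), pset)
            reports = []
            for lvl, hs in prios.items():
                rep = conservation_gaps(hs, coverage, cfg.gap_threshold,
                                        name=f"priority_{lvl}")
                reports.append(rep)
            for cat in ("neo", "paleo", "mixed", "super"):
                cells = cls.cells_in(cat)
                rep = conservation_gaps(cells, coverage, cfg.gap_threshold,
                                        name=f"canape_{cat}")
                reports.append(rep)
            gdf = pd.DataFrame([
                {"set": r.name, "n_cells": len(r.coverage),
                 "n_gaps": len(r.gaps),
                 "overlap_pct": (np.nan if r.overlap_pct is None
                                 else r.overlap_pct)}
                for r in reports])
            emit("gaps.csv", lambda p: gdf.to_csv(p, index=False))
            gap_cells = pd.DataFrame(
                [{"set": r.name, "cell": int(c)} for r in reports
                 for c in r.gaps])
            emit("gap_cells.csv", lambda p: gap_cells.to_csv(p, index=False))

        # -- SAR ---------------------------------------------------------------
        stage = "sar"
        if cfg.file_mode and cfg.predictors:
            ptab = pd.read_csv(cfg.predictors).set_index("cell")
            X_all = standardize(ptab)
            coords = grid.centroids(ptab.index.to_numpy())
            responses = {
                name: m.loc[ptab.index, name].to_numpy()
                for name in ("SR", "ER", "CWE_NAT", "CWE_END", "PE_obs", "RPE")
                if name in m.columns and m.loc[ptab.index, name].notna().all()
            }
            tables, truth = [], None
            for name, yv in responses.items():
                fit = select_sar(yv, X_all, coords,
                                 list(cfg.sar_k_candidates), response=name)
                tables.append(fit.coefficient_table())
        elif not cfg.file_mode:
            y, X, truth = simulate_sar_surface(sc, grid)
            fit = select_sar(y, standardize(X), grid.centroids(),
                             list(cfg.sar_k_candidates), response="synthetic_y")
            tables = [fit.coefficient_table()]
            # also explain the observed endemism surface with the predictors
            common = m.index.to_numpy()
            Xc = standardize(X.iloc[common])
            yv = m["CWE_NAT"].to_numpy()
            fit2 = select_sar(yv, Xc, grid.centroids(common),
                              list(cfg.sar_k_candidates), response="CWE_NAT")
            tables.append(fit2.coefficient_table())
            emit("sar_truth.json", lambda p: p.write_text(json.dumps({
                **truth, "lambda_hat": fit.lam, "k_hat": fit.k,
                "beta_hat": fit.beta.tolist(),
            }, indent=1)))
        else:
            tables = []
        if tables:
            sdf = pd.concat(tables, ignore_index=True)
            emit("sar.csv", lambda p: sdf.to_csv(p, index=False))

    except Exception as exc:
        (out / "error_manifest.json").write_text(json.dumps({
            "failed_stage": stage, "error": str(exc),
            "completed_files": [str(p.relative_to(out)) for p in written],
        }, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(cfg),
        "stages": list(STAGES),
        "files": {str(p.relative_to(out)): _sha256(p)
                  for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return out
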