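"""Per-cell endemism metrics.

SR/ER are plain richness counts; WE weights each taxon by the inverse of
its range (number of occupied cells), CWE divides WE by richness; PE sums
branch length over branch range for the branches spanning a cell's taxa,
and RPE compares PE on the observed tree against PE on a comparison tree
with identical topology and equalized branch lengths.

Native-taxon metrics (SR, WE, CWE_NAT) use all taxa; the phylogenetic
metrics (PE, RPE) and the *_END variants use the endemic subset only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .grid import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "richness",
    "weighted_endemism",
    "corrected_weighted_endemism",
    "BranchIncidence",
    "branch_incidence",
    "phylogenetic_endemism",
    "make_comparison_tree",
    "relative_phylogenetic_endemism",
    "cell_metrics",
]


def richness(matrix: CommunityMatrix, endemic_only: bool = False) -> np.ndarray:
    """Per-cell taxon counts (SR, or ER with ``endemic_only``)."""
    return matrix.er if endemic_only else matrix.sr


def weighted_endemism(
    matrix: CommunityMatrix,
    endemic_only: bool = False,
    range_scale: float = 1.0,
) -> np.ndarray:
    """WE_j = sum over taxa present in cell j of 1 / (range_i * range_scale).

    ``range_scale`` converts cell counts into other range units (e.g. km^2
    per cell); with the default 1 the conservation identity
    sum_j WE_j == number of selected taxa holds exactly.
    """
    sel = matrix.endemic_mask if endemic_only else np.ones(matrix.n_taxa, bool)
    if not sel.any():
        raise ValueError("empty taxon selection")
    pres = matrix.presence[:, sel].astype(np.float64)
    ranges = pres.sum(axis=0)
    return pres @ (1.0 / (ranges * range_scale))


def corrected_weighted_endemism(we: np.ndarray, rich: np.ndarray) -> np.ndarray:
    """CWE_j = WE_j / richness_j; cells with zero richness are excluded
    (returned as NaN and logged), never NaN-propagated from division."""
    we = np.asarray(we, dtype=np.float64)
    rich = np.asarray(rich, dtype=np.float64)
    out = np.full_like(we, np.nan)
    ok = rich > 0
    out[ok] = we[ok] / rich[ok]
    if (~ok).any():
        logger.info("corrected_weighted_endemism: excluded %d zero-richness "
                    "cells", int((~ok).sum()))
    return out


@dataclass
class BranchIncidence:
    """Branch x cell incidence for a (matrix, tree) pair.

    ``branch_tips[b, t]`` flags whether tip t descends from branch b, so a
    branch is present in a cell iff any of its descendant tips is. Branch
    order is the tree's postorder; tips' incidences equal their matrix
    columns.
    """

    lengths: np.ndarray        # (n_branches,)
    branch_tips: np.ndarray    # (n_branches, n_taxa) bool
    incidence: np.ndarray      # (n_cells, n_branches) bool
    taxon_ids: list[str]
    cell_ids: np.ndarray

    @property
    def branch_ranges(self) -> np.ndarray:
        """Cells per branch, from the stored incidence."""
        return self.incidence.sum(axis=0).astype(np.int64)

    def incidence_for(self, presence: np.ndarray) -> np.ndarray:
        """Recompute cell x branch incidence for another presence matrix
        over the same taxa (used by the randomization nulls)."""
        return (presence.astype(np.int32) @ self.branch_tips.T.astype(np.int32)) > 0


def _pruned_to_matrix(tree: dendropy.Tree, taxon_ids: list[str]) -> dendropy.Tree:
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxon_ids if t not in tip_labels]
    if missing:
        raise ValueError(
            "matrix taxa missing from tree: " + ", ".join(sorted(missing)))
    tree = tree.clone(depth=1)
    keep = set(taxon_ids)
    if tip_labels - keep:
        tree.retain_taxa_with_labels(sorted(keep))
    return tree


def branch_incidence(
    tree: dendropy.Tree,
    matrix: CommunityMatrix,
    include_root: bool = True,
) -> BranchIncidence:
    """Branch incidence by one postorder sweep: each branch is present
    wherever the union of its children is. Taxa on the tree but absent
    from the matrix are pruned first; matrix taxa missing from the tree
    raise. Zero-length branches are retained (they contribute nothing
    to PE); ``include_root=False`` drops the root's own branch.
    """
    tree = _pruned_to_matrix(tree, matrix.taxon_ids)
    t_index = {t: j for j, t in enumerate(matrix.taxon_ids)}
    n_taxa = matrix.n_taxa

    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder_node_iter():
        if node.parent_node is None and not include_root:
            continue
        tips = np.zeros(n_taxa, dtype=bool)
        if node.is_leaf():
            tips[t_index[node.taxon.label]] = True
        else:
            for child in node.child_nodes():
                tips |= child._px_tips  # filled earlier in postorder
        node._px_tips = tips
        rows.append(tips)
        lengths.append(float(node.edge.length or 0.0))

    branch_tips = np.array(rows, dtype=bool)
    inc = (matrix.presence.astype(np.int32) @ branch_tips.T.astype(np.int32)) > 0
    return BranchIncidence(
        lengths=np.array(lengths, dtype=np.float64),
        branch_tips=branch_tips,
        incidence=inc,
        taxon_ids=list(matrix.taxon_ids),
        cell_ids=matrix.cell_ids.copy(),
    )


def phylogenetic_endemism(
    inc: BranchIncidence, incidence: np.ndarray | None = None
) -> np.ndarray:
    """PE_j = sum over branches b present in cell j of length_b / range_b.

    ``incidence`` overrides the stored cell x branch incidence (branch
    ranges are then recomputed from it), which lets the nulls reuse one
    BranchIncidence across randomized matrices.
    """
    M = inc.incidence if incidence is None else incidence
    r = M.sum(axis=0).astype(np.float64)
    w = np.zeros_like(inc.lengths)
    present = r > 0
    w[present] = inc.lengths[present] / r[present]
    return M.astype(np.float64) @ w


def make_comparison_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Identical topology with every branch length set to T/N (T = total
    length, N = branch count), preserving total tree length — the
    comparison tree of the RPE ratio."""
    lengths = [e.length for e in tree.preorder_edge_iter() if e.length is not None]
    total = float(sum(lengths))
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    mean_len = total / len(lengths)
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = mean_len
    return out


def relative_phylogenetic_endemism(
    pe_obs: np.ndarray, pe_alt: np.ndarray
) -> np.ndarray:
    """RPE_j = PE_obs_j / PE_alt_j; > 1 flags locally over-represented long
    (old) branches, < 1 short (young) ones. Cells with PE_alt == 0 are
    excluded (NaN, logged)."""
    pe_obs = np.asarray(pe_obs, dtype=np.float64)
    pe_alt = np.asarray(pe_alt, dtype=np.float64)
    out = np.full_like(pe_obs, np.nan)
    ok = pe_alt > 0
    out[ok] = pe_obs[ok] / pe_alt[ok]
    if (~ok).any():
        logger.info("relative_phylogenetic_endemism: excluded %d cells with "
                    "PE_alt == 0", int((~ok).sum()))
    return out


def cell_metrics(
    matrix: CommunityMatrix,
    tree: dendropy.Tree | None = None,
    range_scale: float = 1.0,
    include_root: bool = True,
) -> pd.DataFrame:
    """Per-cell metric table: SR, ER, WE, CWE_NAT, WE_END, CWE_END and —
    when a tree is given — PE_obs, PE_alt, RPE on the endemic subset.

    Phylogenetic and *_END columns are NaN on cells without endemics.
    """
    sr = matrix.sr
    er = matrix.er
    we = weighted_endemism(matrix, range_scale=range_scale)
    df = pd.DataFrame({
        "cell": matrix.cell_ids,
        "SR": sr,
        "ER": er,
        "WE": we,
        "CWE_NAT": corrected_weighted_endemism(we, sr),
    }).set_index("cell")

    if matrix.endemic_mask.any():
        end = matrix.endemic_submatrix()
        we_end = weighted_endemism(end, range_scale=range_scale)
        df.loc[end.cell_ids, "WE_END"] = we_end
        df.loc[end.cell_ids, "CWE_END"] = corrected_weighted_endemism(
            we_end, end.sr)
        if tree is not None:
            inc = branch_incidence(tree, end, include_root=include_root)
            pe_obs = phylogenetic_endemism(inc)
            inc_alt = branch_incidence(
                make_comparison_tree(tree), end, include_root=include_root)
            pe_alt = phylogenetic_endemism(inc_alt)
            df.loc[end.cell_ids, "PE_obs"] = pe_obs
            df.loc[end.cell_ids, "PE_alt"] = pe_alt
            df.loc[end.cell_ids, "RPE"] = relative_phylogenetic_endemism(
                pe_obs, pe_alt)
    return df.reset_index()
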