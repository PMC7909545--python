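"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest

from phyloendemix.grid import CommunityMatrix, GridSpec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_tree(n_tips: int, pyrng: random.Random) -> dendropy.Tree:
    """A random Yule tree with tips t0..t{n-1}."""
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=pyrng)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    return tree


def random_matrix(
    n_cells: int, n_taxa: int, rng: np.random.Generator, p: float = 0.3
) -> CommunityMatrix:
    """Random presence/absence with every taxon and every cell occupied."""
    pres = (rng.random((n_cells, n_taxa)) < p).astype(np.uint8)
    for j in range(n_taxa):  # every taxon in >= 1 cell
        if pres[:, j].sum() == 0:
            pres[rng.integers(n_cells), j] = 1
    for i in range(n_cells):  # every cell holds >= 1 taxon
        if pres[i].sum() == 0:
            pres[i, rng.integers(n_taxa)] = 1
    return CommunityMatrix(
        presence=pres,
        cell_ids=np.arange(n_cells),
        taxon_ids=[f"t{j}" for j in range(n_taxa)],
        endemic_mask=np.ones(n_taxa, dtype=bool),
        grid=None,
    )


def random_instance(seed: int, max_tips: int = 25, max_cells: int = 30):
    """One random (tree, matrix) pair with matched taxa."""
    nprng = np.random.default_rng(seed)
    pyrng = random.Random(seed)
    n_tips = int(nprng.integers(4, max_tips + 1))
    n_cells = int(nprng.integers(3, max_cells + 1))
    tree = random_tree(n_tips, pyrng)
    matrix = random_matrix(n_cells, n_tips, nprng)
    return tree, matrix


def brute_force_pe(tree: dendropy.Tree, matrix: CommunityMatrix,
                   include_root: bool = True) -> np.ndarray:
    """Independent per-cell PE: explicit loops over branches and cells.

    For every branch, its descendant tip set is collected by walking the
    subtree; the branch is present in a cell iff the cell holds any of
    those tips; PE_j sums length/range over the branches present in j.
    """
    t_index = {t: j for j, t in enumerate(matrix.taxon_ids)}
    n_cells = matrix.n_cells
    pe = np.zeros(n_cells)
    branches = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None and not include_root:
            continue
        tips = [t_index[lf.taxon.label] for lf in node.leaf_iter()
                if lf.taxon.label in t_index]
        if not tips:
            continue
        length = float(node.edge.length or 0.0)
        present = []
        for i in range(n_cells):
            if any(matrix.presence[i, t] for t in tips):
                present.append(i)
        branches.append((length, present))
    for length, present in branches:
        r = len(present)
        if r == 0:
            continue
        for i in present:
            pe[i] += length / r
    return pe
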