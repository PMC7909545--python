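"""Megatree completion: graft taxa missing from a phylogeny next to a
randomly chosen congener (subspecies next to their parent species).

The congener's terminal branch of length l is split at ``fraction * l``
from the tip (default midpoint), the new tip attached there with the same
pendant length, preserving the congener's root-to-tip depth. Grafts are
applied sequentially, and a freshly grafted tip is a legal congener target
for later grafts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy

__all__ = ["GraftEntry", "graft_missing_taxa", "genus_of"]


@dataclass(frozen=True)
class GraftEntry:
    taxon_id: str
    genus: str | None = None  # default: parsed from taxon_id
    parent_species: str | None = None  # subspecies case


def genus_of(label: str) -> str:
    """Genus = token before the first underscore or space."""
    for sep in ("_", " "):
        if sep in label:
            return label.split(sep, 1)[0]
    return label


def graft_missing_taxa(
    tree: dendropy.Tree,
    taxa: list[GraftEntry],
    seed: int,
    fraction: float = 0.5,
) -> dendropy.Tree:
    """Return a new tree with every entry grafted next to a congener.

    Parameters
    ----------
    taxa
        Entries to graft, in order. Species-level entries pick a uniform
        random congener tip (same genus); subspecies entries attach to
        their ``parent_species`` tip.
    seed
        Seeds the congener choice; identical seeds give bit-identical
        Newick output.
    fraction
        Where on the target's terminal branch the new node sits, as the
        pendant fraction retained by both tips (0.5 = midpoint).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = random.Random(seed)
    tree = tree.clone(depth=1)
    ns = tree.taxon_namespace
    tips_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    orphans = []
    for entry in taxa:
        if entry.taxon_id in tips_by_label:
            raise ValueError(f"duplicate tip label {entry.taxon_id!r}")
        if entry.parent_species is not None:
            target = tips_by_label.get(entry.parent_species)
            if target is None:
                orphans.append(entry.taxon_id)
                continue
        else:
            genus = entry.genus or genus_of(entry.taxon_id)
            congeners = sorted(
                lbl for lbl in tips_by_label if genus_of(lbl) == genus
            )
            if not congeners:
                orphans.append(entry.taxon_id)
                continue
            target = tips_by_label[rng.choice(congeners)]

        length = target.edge.length or 0.0
        parent = target.parent_node
        pendant = length * fraction
        parent.remove_child(target)
        joint = parent.new_child(edge_length=length - pendant)
        joint.add_child(target)
        target.edge.length = pendant
        new_taxon = ns.new_taxon(label=entry.taxon_id)
        new_tip = joint.new_child(taxon=new_taxon, edge_length=pendant)
        tips_by_label[entry.taxon_id] = new_tip

    if orphans:
        raise ValueError(
            "taxa with no congener and no parent species tip: "
            + ", ".join(orphans)
        )
    return tree
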