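"""Ancestral splicing-event counts on a rooted species tree.

A conserved-event cluster is evidence that the event existed in the common
ancestor of the species it spans.  For an internal node ``v`` with ingroup
clade ``I`` (the species descending from ``v``) and sister clade ``S`` (the
species of ``v``'s sibling subtree), a cluster is counted at ``v`` when it
contains at least one sister-clade species and at least ``min_ingroup``
ingroup species: under parsimony the event was then present in the ancestor
at ``v``'s parent divergence.  ``min_ingroup=1`` is the permissive
stringency; ``min_ingroup=2`` guards against single convergent gains and
gives a lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy

from .conservation import ConservedEventCluster

__all__ = ["SpeciesTree", "count_ancestral_events"]


@dataclass
class _Node:
    label: str
    ingroup: frozenset[str]
    sister: frozenset[str]


class SpeciesTree:
    """A rooted species tree with per-node ingroup and sister clades.

    Counts are attached to every non-root node (each represents the
    divergence at its parent); leaf labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in species tree")
        self.species = frozenset(labels)
        self.nodes: list[_Node] = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ingroup = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            sister = frozenset(
                leaf.taxon.label
                for sib in node.parent_node.child_nodes()
                if sib is not node
                for leaf in sib.leaf_iter()
            )
            label = node.taxon.label if node.taxon else (
                node.label or "+".join(sorted(ingroup))
            )
            self.nodes.append(_Node(label=label, ingroup=ingroup, sister=sister))

    @classmethod
    def from_newick(cls, source: str) -> "SpeciesTree":
        """Build from a newick string or a path to a newick file."""
        import os

        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls(tree)

    def internal_nodes(self) -> list[_Node]:
        return [n for n in self.nodes if len(n.ingroup) >= 2]


def count_ancestral_events(
    tree: SpeciesTree,
    clusters: Sequence[ConservedEventCluster],
    min_ingroup: int = 1,
) -> dict[str, int]:
    """Per-node ancestral event counts at the given stringency.

    Raises when a cluster names a species absent from the tree.
    """
    if min_ingroup < 1:
        raise ValueError("min_ingroup must be >= 1")
    unknown = set()
    for cl in clusters:
        unknown |= cl.species_set - tree.species
    if unknown:
        raise ValueError(
            f"cluster species not in tree: {sorted(unknown)}"
        )
    counts: dict[str, int] = {}
    for node in tree.internal_nodes():
        counts[node.label] = sum(
            1
            for cl in clusters
            if cl.species_set & node.sister
            and len(cl.species_set & node.ingroup) >= min_ingroup
        )
    return counts
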