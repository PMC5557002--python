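"""Dated, rooted trees (chronograms) with node ages and posterior support.

A :class:`Chronogram` wraps a rooted ``dendropy.Tree`` whose branch lengths
are in millions of years (Ma).  Node ages are distances to the tips, so an
ultrametric tree has all tips at age 0; ultrametricity is validated on
construction.  Posterior clade support (PP) is carried as a per-node
attribute, parsed from ``[&pp=...]`` hot comments when present.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import dendropy

__all__ = ["Chronogram"]

ULTRAMETRIC_TOL = 1e-6


class Chronogram:
    """Rooted ultrametric dated tree with posterior support values."""

    def __init__(self, tree: dendropy.Tree, *, tol: float = 1e-3):
        if tree.seed_node is None:
            raise ValueError("empty tree")
        tree.is_rooted = True
        self.tree = tree
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
        self.depth = float(depth)
        for node in tree.preorder_node_iter():
            node.age = self.depth - float(node.root_distance)
        spread = max(abs(leaf.age) for leaf in tree.leaf_node_iter())
        if spread > max(tol, ULTRAMETRIC_TOL * max(1.0, self.depth)):
            raise ValueError(f"tree is not ultrametric: tip ages spread {spread}")
        for leaf in tree.leaf_node_iter():
            leaf.age = 0.0
        for node in tree.preorder_node_iter():
            if not hasattr(node, "pp"):
                node.pp = _extract_pp(node)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path, *, tol: float = 1e-3) -> "Chronogram":
        """Read a Newick chronogram; ``[&pp=..]`` comments become node support."""
        path = Path(source) if not str(source).lstrip().startswith("(") else None
        if path is not None and path.exists():
            tree = dendropy.Tree.get(path=str(path), schema="newick",
                                     extract_comment_metadata=True,
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=str(source), schema="newick",
                                     extract_comment_metadata=True,
                                     preserve_underscores=True)
        return cls(tree, tol=tol)

    def to_newick(self) -> str:
        """Newick string with ``[&pp=..,age=..]`` annotations on internal nodes."""
        for node in self.tree.preorder_node_iter():
            node.annotations.drop()
            if node.pp is not None:
                node.annotations.add_new("pp", float(node.pp))
            node.annotations.add_new("age", round(float(node.age), 6))
        return self.tree.as_string(schema="newick", suppress_annotations=False,
                                   suppress_rooting=True).strip()

    # -- accessors ---------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def leaves(self):
        return list(self.tree.leaf_node_iter())

    def internal_nodes(self, exclude_root: bool = False):
        nodes = [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]
        if exclude_root:
            nodes = [n for n in nodes if n is not self.tree.seed_node]
        return nodes

    def node_by_bipartition(self, tips: Iterable[str]):
        """Internal node whose descendant tip set equals ``tips`` (or None)."""
        want = frozenset(tips)
        for node in self.internal_nodes():
            if self.bipartition(node) == want:
                return node
        return None

    @staticmethod
    def bipartition(node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def mrca(self, tips: Iterable[str]):
        taxa = [t for t in self.tree.taxon_namespace if t.label in set(tips)]
        return self.tree.mrca(taxa=taxa)

    def set_support(self, support: Mapping[frozenset, float]) -> None:
        """Assign PP values by descendant-tip bipartition."""
        for node in self.internal_nodes():
            bip = self.bipartition(node)
            if bip in support:
                node.pp = float(support[bip])

    def __len__(self) -> int:
        return len(self.taxa)


def _extract_pp(node) -> float | None:
    for key in ("pp", "PP", "posterior"):
        v = node.annotations.get_value(key)
        if v is not None:
            try:
                return float(v)
            except (TypeError, ValueError):
                pass
    # support stored as a bare internal-node label, the other common convention
    if not node.is_leaf() and node.label:
        try:
            return float(node.label)
        except ValueError:
            pass
    return None
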