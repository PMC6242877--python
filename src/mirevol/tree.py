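"""Rooted, dated species trees.

A :class:`DatedTree` is a rooted tree whose branch lengths are in million
years (Myr).  It is the substrate for Dollo gain/loss reconstruction and for
per-branch net gain rates, so every non-root node must have a strictly
positive branch length and every branch needs a stable identifier.

Branch naming convention: the branch above a node is named after that node —
the species name for a terminal branch, the '+'-joined sorted leaf set for an
internal branch (e.g. ``cow+pig``), and ``root`` for the synthetic stem above
the root (used when a character is reconstructed as present at the root).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

ROOT_BRANCH = "root"


@dataclass
class TreeNode:
    """One node of a rooted tree; ``length`` is the branch above it, in Myr."""

    label: str
    length: float = 0.0
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


class DatedTree:
    """Rooted tree with Myr branch lengths and unique leaf names.

    Parameters
    ----------
    root:
        Root :class:`TreeNode`; internal nodes are (re)labelled by their
        sorted leaf sets so that branch identifiers are reproducible across
        runs and independent of any labels in the source Newick.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._relabel_internal()
        names = [n.label for n in root.leaves()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {', '.join(dupes)}")
        self.leaf_names = names
        self._nodes_by_label = {n.label: n for n in self.preorder()}

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        root = dt.seed_node
        if len(root.child_nodes()) != 2:
            raise ValueError(
                "tree must be rooted with a bifurcating root "
                f"(root has {len(root.child_nodes())} children)"
            )

        def convert(dnode, parent=None) -> TreeNode:
            label = dnode.taxon.label if dnode.taxon is not None else ""
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            node = TreeNode(label=label, length=float(length), parent=parent)
            for child in dnode.child_nodes():
                node.children.append(convert(child, node))
            return node

        tree = cls(convert(root))
        for node in tree.preorder():
            if node is not tree.root and node.length <= 0:
                raise ValueError(
                    f"branch above {node.label!r} has non-positive length "
                    f"{node.length}"
                )
        return tree

    def _relabel_internal(self) -> None:
        for node in self.postorder():
            if not node.is_leaf:
                node.label = "+".join(sorted(l.label for l in node.leaves()))

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for c in node.children:
                yield from walk(c)
            yield node

        yield from walk(self.root)

    # -- queries -------------------------------------------------------

    def node(self, label: str) -> TreeNode:
        try:
            return self._nodes_by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r}") from None

    def branch_labels(self) -> list[str]:
        """All branch identifiers: one per non-root node, plus the root stem."""
        return [n.label for n in self.preorder() if n is not self.root] + [
            ROOT_BRANCH
        ]

    def mrca(self, leaf_names: set[str]) -> TreeNode:
        """Most recent common ancestor of the named leaves."""
        missing = leaf_names - set(self.leaf_names)
        if missing:
            raise KeyError(f"unknown leaves: {', '.join(sorted(missing))}")
        if not leaf_names:
            raise ValueError("mrca of an empty leaf set")
        node = self._nodes_by_label[next(iter(sorted(leaf_names)))]
        while not leaf_names <= {l.label for l in node.leaves()}:
            node = node.parent
        return node

    def leaves_below(self, branch_label: str) -> set[str]:
        if branch_label == ROOT_BRANCH:
            return set(self.leaf_names)
        return {l.label for l in self.node(branch_label).leaves()}

    def is_strictly_below(self, branch_label: str, ancestor_label: str) -> bool:
        """True iff ``branch_label`` lies strictly below ``ancestor_label``."""
        if branch_label == ROOT_BRANCH:
            return False
        if ancestor_label == ROOT_BRANCH:
            return True
        node = self.node(branch_label).parent
        while node is not None:
            if node.label == ancestor_label:
                return True
            node = node.parent
        return False

    def branch_length(self, branch_label: str, root_stem_length: float = 1.0) -> float:
        if branch_label == ROOT_BRANCH:
            return root_stem_length
        return self.node(branch_label).length

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner})"
            return f"({inner}):{node.length:g}"

        return fmt(self.root) + ";"
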