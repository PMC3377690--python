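"""Rooted trees and the reference species tree.

The species tree is the fixed coordinate system of a study: every loss,
pseudogenization and gene-birth event is ultimately placed on one of its
branches.  It must be rooted, binary and ultrametric with branch lengths in
million years (MY), so that the depth of any internal node below the leaves is
a divergence age.
"""

from __future__ import annotations

import io
from typing import Iterator, Optional, Sequence

import dendropy

from .errors import DomainError, FormatError, LookupError_, StructureError, ValidationError

__all__ = ["TreeNode", "SpeciesTree", "parse_newick_node", "node_to_newick"]


class TreeNode:
    """A node of a rooted tree; used for species trees and gene trees alike."""

    __slots__ = ("name", "length", "parent", "children", "label", "mapping")

    def __init__(self, name: str = "", length: Optional[float] = None):
        self.name = name
        self.length = length          # branch length to the parent (None at root)
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []
        self.label: Optional[str] = None    # gene trees: "speciation" | "duplication"
        self.mapping: Optional[str] = None  # gene trees: species-tree node name

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def copy(self) -> "TreeNode":
        n = TreeNode(self.name, self.length)
        n.label, n.mapping = self.label, self.mapping
        for c in self.children:
            n.add_child(c.copy())
        return n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


def parse_newick_node(text: str) -> TreeNode:
    """Parse a Newick string into a TreeNode tree (via dendropy).

    Unnamed internal nodes are auto-named ``N1``, ``N2``, ... in preorder.
    NHX-style comments are ignored here; see formats_io.read_annotated_tree.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            name = dnode.taxon.label
        else:
            name = dnode.label or ""
        node = TreeNode(name, dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    counter = 0
    seen = set()
    for n in root.preorder():
        if not n.name:
            counter += 1
            while f"N{counter}" in seen:
                counter += 1
            n.name = f"N{counter}"
        seen.add(n.name)
    return root


def node_to_newick(node: TreeNode, with_lengths: bool = True,
                   comment_for=None) -> str:
    """Serialize a TreeNode tree to Newick; optional per-node NHX comment hook."""

    def fmt_len(x: Optional[float]) -> str:
        if x is None or not with_lengths:
            return ""
        if float(x) == int(x):
            return f":{int(x)}"
        return f":{x:g}"

    def rec(n: TreeNode) -> str:
        com = comment_for(n) if comment_for else ""
        if n.is_leaf:
            return f"{n.name}{fmt_len(n.length)}{com}"
        inner = ",".join(rec(c) for c in n.children)
        return f"({inner}){n.name}{fmt_len(n.length)}{com}"

    return rec(node) + ";"


class SpeciesTree:
    """Rooted binary ultrametric species tree with branch lengths in MY."""

    #: relative tolerance on leaf-depth equality, as a fraction of root depth
    ULTRAMETRIC_RTOL = 1e-6

    def __init__(self, root: TreeNode, validate: bool = True):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        for n in root.preorder():
            if n.name in self._index:
                raise ValidationError(f"duplicate node name {n.name!r}")
            self._index[n.name] = n
        self._depth: dict[str, float] = {}  # distance from root
        self._compute_depths()
        if validate:
            self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, validate: bool = True) -> "SpeciesTree":
        return cls(parse_newick_node(text), validate=validate)

    def _compute_depths(self) -> None:
        self._depth[self.root.name] = 0.0
        for n in self.root.preorder():
            if n is self.root:
                continue
            if n.length is None:
                raise FormatError(f"missing branch length on node {n.name!r}")
            self._depth[n.name] = self._depth[n.parent.name] + float(n.length)

    def validate(self) -> None:
        for n in self.root.preorder():
            if not n.is_leaf and len(n.children) != 2:
                raise StructureError(
                    f"species tree must be binary; node {n.name!r} has "
                    f"{len(n.children)} children")
        leaves = self.root.leaves()
        ref = self._depth[leaves[0].name]  # first leaf sets the reference depth
        tol = max(self.ULTRAMETRIC_RTOL * max(ref, 1.0), 1e-12)
        for leaf in leaves[1:]:
            d = self._depth[leaf.name]
            if abs(d - ref) > tol:
                raise ValidationError(
                    f"tree not ultrametric: leaf {leaf.name!r} at depth "
                    f"{d:g}, expected {ref:g}")

    # -- basic queries -----------------------------------------------------

    def node(self, name: str) -> TreeNode:
        try:
            return self._index[name]
        except KeyError:
            raise LookupError_(f"unknown node {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    @property
    def height(self) -> float:
        """Root depth below the present (MY)."""
        return max(self._depth[l] for l in self.leaf_names)

    def depth(self, name: str) -> float:
        """Distance of a node from the root."""
        self.node(name)
        return self._depth[name]

    def age(self, name: str) -> float:
        """Age of a node below the present (MY); 0 for leaves."""
        return self.height - self.depth(name)

    def is_ancestor_or_self(self, ancestor: str, descendant: str) -> bool:
        n = self.node(descendant)
        a = self.node(ancestor)
        while n is not None:
            if n is a:
                return True
            n = n.parent
        return False

    # -- spec operations ---------------------------------------------------

    def lca(self, names: Sequence[str]) -> str:
        """Lowest common ancestor of a set of node names; lca({x}) = x."""
        names = list(names)
        if not names:
            raise DomainError("lca of empty set")
        paths = []
        for name in names:
            n = self.node(name)
            path = []
            while n is not None:
                path.append(n.name)
                n = n.parent
            paths.append(list(reversed(path)))
        lca = None
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca

    def divergence_time(self, a: str, b: str) -> float:
        """Age (MY) of the LCA of two distinct leaves below the present."""
        if a == b:
            raise DomainError("divergence_time requires two distinct species")
        na, nb = self.node(a), self.node(b)
        if not na.is_leaf or not nb.is_leaf:
            raise DomainError("divergence_time is defined on leaves")
        return self.age(self.lca([a, b]))

    def species_under(self, ancestor: str) -> set[str]:
        """All leaf names of the subtree rooted at ancestor."""
        return set(self.node(ancestor).leaf_names())

    def branch_path(self, ancestor: str, descendant: str) -> list[tuple[str, str]]:
        """Branches (parent, child) from ancestor to descendant, top-down."""
        a, d = self.node(ancestor), self.node(descendant)
        path = []
        n = d
        while n is not a:
            if n.parent is None:
                raise DomainError(
                    f"{descendant!r} is not a descendant of {ancestor!r}")
            path.append((n.parent.name, n.name))
            n = n.parent
        return list(reversed(path))

    def branches_under(self, ancestor: str) -> list[tuple[str, str]]:
        """All branches (parent, child) in the subtree rooted at ancestor."""
        out = []
        for n in self.node(ancestor).preorder():
            for c in n.children:
                out.append((n.name, c.name))
        return out

    def to_newick(self) -> str:
        return node_to_newick(self.root)
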