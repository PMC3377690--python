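"""Gene phylogenies and their reconciliation with the species tree.

A gene family is summarized as a rooted binary gene tree whose internal nodes
are labeled speciation or duplication by LCA mapping against the species
tree.  Ortholog groups — the leaves under a speciation node established at a
chosen ancestor — are read off the reconciled tree, and the species of the
study set with no member in the group become candidates for lineage-specific
loss.

Tree construction here is distance-based (pairwise distances from a multiple
protein alignment, then neighbor joining); downstream logic consumes only the
labeled topology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import mafft_msa
from .errors import DomainError, LookupError_
from .formats_io import SequenceRecord
from .species_tree import SpeciesTree, TreeNode

__all__ = [
    "ReconciledGeneTree", "OrthologGroup",
    "pairwise_distances", "build_nj", "root_gene_tree", "reconcile",
    "extract_ortholog_group", "missing_species", "enumerate_subfamily_roots",
    "build_reconciled_tree",
]

MAX_DISTANCE = 5.0  # cap for saturated pairs (p >= 0.95)


@dataclass
class ReconciledGeneTree:
    """Rooted binary gene tree with speciation/duplication labels.

    Each internal node's ``mapping`` is the species-tree LCA of its leaf
    species; ``label`` is "duplication" iff the mapping equals a child's.
    """

    root: TreeNode
    species_of: dict  # leaf name -> species code
    species_tree: SpeciesTree

    def leaf(self, name: str) -> TreeNode:
        for lf in self.root.leaves():
            if lf.name == name:
                return lf
        raise LookupError_(f"leaf {name!r} not in gene tree")

    def duplication_count(self) -> int:
        return sum(1 for n in self.root.preorder()
                   if not n.is_leaf and n.label == "duplication")


@dataclass
class OrthologGroup:
    """Genes descending from one speciation node of the reconciled tree."""

    members: set  # of (species, gene_id)
    defining_node: Optional[TreeNode]
    mapped_ancestor: Optional[str]

    @property
    def species(self) -> set:
        return {sp for sp, _ in self.members}


# ---------------------------------------------------------------------------
# Distances

def pairwise_distances(records: Sequence[SequenceRecord],
                       max_distance: float = MAX_DISTANCE,
                       ) -> tuple[np.ndarray, list[str]]:
    """Distance matrix from a multiple protein alignment.

    Sequences are globally aligned together; each pair is scored over its
    mutually ungapped columns as d = -ln(1 - p) with p the mismatch
    proportion.  Saturated pairs (p >= 0.95) are capped at ``max_distance``.
    """
    if len(records) < 3:
        raise DomainError("pairwise_distances requires at least 3 sequences")
    rows = mafft_msa([(r.id, r.seq) for r in records], kind="protein")
    labels = [name for name, _ in rows]
    arr = np.array([list(seq) for _, seq in rows])
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != "-") & (arr[j] != "-")
            total = int(both.sum())
            if total == 0:
                p = 1.0
            else:
                p = float((arr[i][both] != arr[j][both]).sum()) / total
            if p >= 0.95:
                warnings.warn(
                    f"distance capped for saturated pair ({labels[i]}, {labels[j]})")
                d = max_distance
            else:
                d = -math.log(1.0 - p)
            dist[i, j] = dist[j, i] = d
    return dist, labels


# ---------------------------------------------------------------------------
# Neighbor joining

def build_nj(matrix: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    The unrooted tree is represented as a TreeNode whose root has three
    children (the final NJ star).  Ties on the Q criterion are broken by the
    lexicographically smallest label pair, where a cluster is identified by
    the smallest leaf label it contains.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if n < 3:
        raise DomainError("build_nj requires at least 3 taxa")
    if matrix.shape != (n, n):
        raise DomainError("matrix shape does not match labels")
    if np.isnan(matrix).any():
        raise DomainError("NaN in distance matrix")
    if not np.allclose(matrix, matrix.T):
        raise DomainError("distance matrix not symmetric")

    nodes = [TreeNode(lab) for lab in labels]
    reps = list(labels)  # representative (min leaf label) per active cluster
    D = matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                key = (q, pair_key)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        new = TreeNode("")
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        # grow matrix with the new cluster
        newrow = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    root = TreeNode("")
    nodes[a].length = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    nodes[b].length = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    nodes[c].length = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    for k in sorted((a, b, c), key=lambda k: reps[k]):
        root.add_child(nodes[k])
    return root


# ---------------------------------------------------------------------------
# Rooting and reconciliation

def _adjacency(root: TreeNode):
    """Undirected adjacency of an (un)rooted TreeNode representation."""
    idx = {}
    adj = {}
    names = {}

    def visit(n: TreeNode):
        idx[id(n)] = len(idx)
        adj[idx[id(n)]] = []
        names[idx[id(n)]] = n.name
        for c in n.children:
            visit(c)
            u, v = idx[id(n)], idx[id(c)]
            w = c.length if c.length is not None else 0.0
            adj[u].append((v, w))
            adj[v].append((u, w))

    visit(root)
    return adj, names


def _edges(adj):
    out = []
    for u, nbrs in adj.items():
        for v, w in nbrs:
            if u < v:
                out.append((u, v, w))
    return out


def _build_rooted(adj, names, u, v, w) -> TreeNode:
    """Root the undirected tree on edge (u, v), splitting its length."""

    def hang(node, parent) -> TreeNode:
        t = TreeNode(names[node])
        for nbr, length in adj[node]:
            if nbr == parent:
                continue
            child = hang(nbr, node)
            child.length = length
            t.add_child(child)
        return t

    root = TreeNode("")
    left = hang(u, v)
    left.length = w / 2
    right = hang(v, u)
    right.length = w / 2
    root.add_child(left)
    root.add_child(right)
    _suppress_unary(root)
    return root


def _suppress_unary(root: TreeNode) -> None:
    """Splice out degree-2 artifacts left by unrooting a rooted input."""
    changed = True
    while changed:
        changed = False
        for node in list(root.preorder()):
            if node is root or node.is_leaf or len(node.children) != 1:
                continue
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            parent.children[parent.children.index(node)] = child
            child.parent = parent
            changed = True


def reconcile(gene_root: TreeNode, species_tree: SpeciesTree,
              species_of: dict) -> ReconciledGeneTree:
    """LCA-map every internal node and label it speciation/duplication."""
    for lf in gene_root.leaves():
        sp = species_of.get(lf.name)
        if sp is None or sp not in species_tree:
            raise LookupError_(f"leaf {lf.name!r}: unknown species {sp!r}")
    for node in gene_root.postorder():
        if node.is_leaf:
            node.mapping = species_of[node.name]
            node.label = None
        else:
            node.mapping = species_tree.lca([c.mapping for c in node.children])
            node.label = ("duplication"
                          if any(c.mapping == node.mapping for c in node.children)
                          else "speciation")
    return ReconciledGeneTree(gene_root, dict(species_of), species_tree)


def root_gene_tree(unrooted: TreeNode, species_tree: SpeciesTree,
                   species_of: dict) -> TreeNode:
    """Choose the root minimizing inferred duplications after reconciliation.

    Ties are broken by the midpoint criterion (most balanced maximal
    root-to-leaf distances), then by the lexicographically smallest leaf set
    of the left child.
    """
    if len(unrooted.leaves()) < 3:
        raise DomainError("rooting requires at least 3 leaves")
    adj, names = _adjacency(unrooted)
    best = None
    for u, v, w in sorted(_edges(adj)):
        rooted = _build_rooted(adj, names, u, v, w)
        rec = reconcile(rooted, species_tree, species_of)
        dups = rec.duplication_count()
        side_heights = []
        for child in rooted.children:
            h = max(_leaf_depth(child, 0.0))
            side_heights.append(h + (child.length or 0.0))
        balance = abs(side_heights[0] - side_heights[1])
        left_leaves = tuple(sorted(rooted.children[0].leaf_names()))
        key = (dups, balance, left_leaves)
        if best is None or key < best[0]:
            best = (key, rooted)
    return best[1]


def _leaf_depth(node: TreeNode, acc: float) -> list[float]:
    if node.is_leaf:
        return [acc]
    out = []
    for c in node.children:
        out.extend(_leaf_depth(c, acc + (c.length or 0.0)))
    return out


def build_reconciled_tree(records: Sequence[SequenceRecord],
                          species_tree: SpeciesTree) -> ReconciledGeneTree:
    """Convenience pipeline: distances -> NJ -> rooting -> reconciliation."""
    dist, labels = pairwise_distances(records)
    species_of = {r.id: r.species for r in records}
    unrooted = build_nj(dist, labels)
    rooted = root_gene_tree(unrooted, species_tree, species_of)
    return reconcile(rooted, species_tree, species_of)


# ---------------------------------------------------------------------------
# Reading groups off the tree

def extract_ortholog_group(tree: ReconciledGeneTree, query_leaf: str,
                           ancestor: str) -> OrthologGroup:
    """Ortholog group containing the query, established at (or, failing that,
    below) the chosen ancestor.

    Among speciation nodes on the query-to-root path mapping to the ancestor
    or one of its descendants, the node whose mapping is closest to the
    ancestor wins; with equal mappings the one nearest the root wins.  An
    empty group (no qualifying node) signals that the gene is not established
    at this ancestor.
    """
    st = tree.species_tree
    if ancestor not in st:
        raise LookupError_(f"unknown ancestor {ancestor!r}")
    leaf = tree.leaf(query_leaf)
    candidates = []
    node = leaf.parent
    while node is not None:
        if node.label == "speciation" and st.is_ancestor_or_self(ancestor, node.mapping):
            candidates.append(node)
        node = node.parent
    if not candidates:
        return OrthologGroup(set(), None, None)
    # minimal species-tree depth == closest to the ancestor from below;
    # later in the walk == nearer the gene-tree root, preferred on ties
    best = min(enumerate(candidates),
               key=lambda t: (st.depth(t[1].mapping), -t[0]))[1]
    members = {(tree.species_of[l.name], l.name) for l in best.leaves()}
    return OrthologGroup(members, best, best.mapping)


def missing_species(group: OrthologGroup, species_tree: SpeciesTree,
                    ancestor: str) -> set:
    """Species under the ancestor with no representative in the group."""
    return species_tree.species_under(ancestor) - group.species


def enumerate_subfamily_roots(tree: ReconciledGeneTree, query_leaf: str,
                              ancestor: str) -> list[TreeNode]:
    """Speciation nodes following a duplication on the query-to-root path.

    These are the establishment points of new sub-families; returned in
    root-to-leaf order, restricted to mappings at or under the ancestor.
    """
    st = tree.species_tree
    leaf = tree.leaf(query_leaf)
    out = []
    node = leaf.parent
    while node is not None:
        parent = node.parent
        if (node.label == "speciation" and parent is not None
                and parent.label == "duplication"
                and st.is_ancestor_or_self(ancestor, node.mapping)):
            out.append(node)
        node = parent
    return list(reversed(out))
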