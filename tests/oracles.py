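"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles, by exhaustive
enumeration or direct recursion, without touching the implementation path it
checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def brute_global_score(a: str, b: str, gap_open: float = -10.0,
                       gap_extend: float = -0.5) -> float:
    """Best global alignment score by explicit recursion over the three
    possible last operations (match, gap-in-a, gap-in-b), end gaps penalized.
    A gap of length L costs -(open + (L-1)*extend)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = last was match/start, 1 = gap in b open, 2 = gap in a open
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, float(_B62[a[i], b[j]]) + rec(i + 1, j + 1, 0))
        if i < len(a):  # a[i] aligned to a gap in b
            cost = gap_extend if state == 1 else gap_open
            best = max(best, cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            best = max(best, cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


# ---------------------------------------------------------------------------
# Random additive trees and split comparison (NJ oracle)

def random_binary_tree(rng, labels):
    """Random rooted binary topology with random positive branch lengths,
    as nested tuples (left, right, length) / (label, length)."""
    nodes = [(lab, round(float(rng.uniform(0.5, 5.0)), 3)) for lab in labels]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        nodes.append(((a, b), round(float(rng.uniform(0.5, 5.0)), 3)))
    return nodes[0]


def path_distances(tree) -> dict:
    """Leaf-to-leaf path-length matrix of a nested-tuple tree."""
    def depths(node, acc):
        payload, length = node
        if isinstance(payload, str):
            return {payload: acc + length}
        out = {}
        for child in payload:
            out.update(depths(child, acc + length))
        return out

    payload, _ = tree
    dist = {}
    def collect(node):
        payload, _ = node
        if isinstance(payload, str):
            return {payload: 0.0}
        maps = [depths(c, 0.0) for c in payload]
        for m1, m2 in itertools.combinations(maps, 2):
            for x, dx in m1.items():
                for y, dy in m2.items():
                    dist[frozenset((x, y))] = dx + dy
        merged = {}
        for c in payload:
            for leaf, d in collect(c).items():
                merged[leaf] = d + c[1]
        return merged

    collect(tree)
    return dist


def tree_splits(tree) -> set:
    """Non-trivial bipartitions (as frozensets of one side) of a
    nested-tuple tree, read as unrooted."""
    all_leaves = set()

    def leaves(node):
        payload, _ = node
        if isinstance(payload, str):
            return {payload}
        out = set()
        for c in payload:
            out |= leaves(c)
        return out

    all_leaves = leaves(tree)
    splits = set()

    def walk(node):
        payload, _ = node
        if isinstance(payload, str):
            return
        for c in payload:
            side = frozenset(leaves(c))
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(min(side, frozenset(all_leaves - side),
                               key=lambda s: sorted(s)))
            walk(c)

    walk(tree)
    return splits


def node_splits(root) -> set:
    """Same, for a pseudotrace TreeNode (unrooted reading)."""
    all_leaves = set(root.leaf_names())
    splits = set()
    for n in root.preorder():
        if n is root or n.is_leaf:
            continue
        side = frozenset(n.leaf_names())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(min(side, frozenset(all_leaves - side),
                           key=lambda s: sorted(s)))
    return splits


# ---------------------------------------------------------------------------
# Reconciliation oracle

def brute_reconcile_labels(gene_root, species_tree, species_of) -> dict:
    """Recompute LCA mappings from scratch via ancestor-set intersection."""
    def ancestors(name):
        out = []
        n = species_tree.node(name)
        while n is not None:
            out.append(n.name)
            n = n.parent
        return out

    labels = {}
    for node in gene_root.postorder():
        if node.is_leaf:
            continue
        leaf_species = {species_of[l.name] for l in node.leaves()}
        anc_lists = [ancestors(sp) for sp in leaf_species]
        common = set(anc_lists[0])
        for lst in anc_lists[1:]:
            common &= set(lst)
        # lowest common ancestor = the common ancestor of maximal depth
        mapping = max(common, key=lambda n: species_tree.depth(n))
        child_mappings = []
        for c in node.children:
            if c.is_leaf:
                child_mappings.append(species_of[c.name])
            else:
                cs = {species_of[l.name] for l in c.leaves()}
                cl = [ancestors(sp) for sp in cs]
                cc = set(cl[0])
                for lst in cl[1:]:
                    cc &= set(lst)
                child_mappings.append(
                    max(cc, key=lambda n: species_tree.depth(n)))
        labels[id(node)] = ("duplication"
                           if mapping in child_mappings else "speciation")
    return labels


# ---------------------------------------------------------------------------
# Sankoff oracles

def brute_sankoff_min_cost(root, leaf_obs, states, cost) -> float:
    """Exhaustive minimum over all ancestral labelings of a TreeNode tree.

    ``leaf_obs`` maps leaf name -> state; ``cost`` maps (parent, child)
    state pairs to a float.
    """
    internals = [n for n in root.preorder() if not n.is_leaf]
    best = float("inf")
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        total = 0.0
        ok = True
        for n in root.preorder():
            if n is root:
                continue
            ps = assign[id(n.parent)]
            cs = (leaf_obs[n.name] if n.is_leaf else assign[id(n)])
            c = cost(ps, cs)
            if c == float("inf"):
                ok = False
                break
            total += c
        if ok:
            best = min(best, total)
    return best


def assignment_cost(root, assign, leaf_obs, cost) -> float:
    """Cost of a given ancestral assignment (by node name)."""
    total = 0.0
    for n in root.preorder():
        if n is root:
            continue
        ps = assign[n.parent.name]
        cs = leaf_obs[n.name] if n.is_leaf else assign[n.name]
        total += cost(ps, cs)
    return total


def brute_dollo_min_losses(tree, presence, birth) -> int:
    """Smallest number of loss branches explaining a presence pattern under
    single-gain, irreversible-loss rules, by exhaustive subset search."""
    branches = tree.branches_under(birth)
    leaves = [l for l in tree.species_under(birth) if l in presence]

    def explained(loss_set):
        for leaf in leaves:
            path = tree.branch_path(birth, leaf)
            n_losses = sum(1 for b in path if b in loss_set)
            if presence[leaf] and n_losses > 0:
                return False
            if not presence[leaf] and n_losses == 0:
                return False
        return True

    for k in range(len(branches) + 1):
        for combo in itertools.combinations(branches, k):
            if explained(set(combo)):
                return k
    raise AssertionError("no loss set explains the pattern")
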