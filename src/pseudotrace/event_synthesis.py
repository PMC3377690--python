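"""Placing loss, pseudogenization and gene-birth events on the species tree.

Per-species verdicts (Present / Saved / Pseudogene / Lost) are turned into
branch-placed events by parsimony.  Simple mode uses Dollo-like parsimony on
presence/absence: a single gene birth at the LCA of the present species and
one irreversible loss on the stem of every maximal absent-only clade.
Complete mode uses Sankoff parsimony over the ancestral states
{Gene, Pseudogene, Absent} with an irreversibility cost matrix (a pseudogene
never reverts to a gene, an absent gene never reappears); every
parent-to-child state change is an event on that branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConsistencyError, DomainError
from .species_tree import SpeciesTree, TreeNode

__all__ = ["LeafState", "EventPlacement", "DEFAULT_COSTS",
           "dollo_losses", "sankoff_states", "place_events"]

ANC_STATES = ("Gene", "Pseudogene", "Absent")
_LEAF_TO_ANC = {"Present": "Gene", "Saved": "Gene",
                "Pseudogene": "Pseudogene", "Lost": "Absent"}
INF = float("inf")

#: irreversible default costs: gene -> pseudogene -> absent, never back
DEFAULT_COSTS = {
    ("Gene", "Gene"): 0, ("Gene", "Pseudogene"): 1, ("Gene", "Absent"): 1,
    ("Pseudogene", "Pseudogene"): 0, ("Pseudogene", "Absent"): 1,
    ("Pseudogene", "Gene"): INF,
    ("Absent", "Absent"): 0, ("Absent", "Gene"): INF,
    ("Absent", "Pseudogene"): INF,
}


@dataclass(frozen=True)
class LeafState:
    species: str
    state: str  # Present | Saved | Pseudogene | Lost

    def __post_init__(self):
        if self.state not in _LEAF_TO_ANC:
            raise DomainError(f"unknown leaf state {self.state!r}")


@dataclass
class EventPlacement:
    branch: tuple  # (parent_name, child_name) on the species tree
    event: str     # gene_loss | pseudogenization | gene_birth
    supporting_mutations: list = field(default_factory=list)


def dollo_losses(presence: dict, tree: SpeciesTree,
                 scope_root: Optional[str] = None
                 ) -> tuple[str, list[tuple[str, str]]]:
    """Dollo-like parsimony on presence/absence.

    Returns (birth_node, loss_branches): the birth is the LCA of all present
    species; each maximal absent-only clade under the birth gets exactly one
    loss on its stem branch.  Absent species outside the birth clade need no
    loss (the gene was never there).
    """
    present = sorted(sp for sp, p in presence.items() if p)
    if not present:
        raise DomainError("Dollo parsimony needs at least one present species")
    birth = tree.lca(present)
    losses: list[tuple[str, str]] = []

    def visit(node: TreeNode) -> None:
        leaves = node.leaf_names()
        considered = [l for l in leaves if l in presence]
        if considered and all(not presence[l] for l in considered):
            losses.append((node.parent.name, node.name))
            return
        for c in node.children:
            visit(c)

    for c in tree.node(birth).children:
        visit(c)
    return birth, sorted(losses)


def sankoff_states(leaf_states: Sequence[LeafState], tree: SpeciesTree,
                   scope_root: Optional[str] = None,
                   costs: dict = DEFAULT_COSTS) -> dict[str, str]:
    """Minimal-cost ancestral states in {Gene, Pseudogene, Absent}.

    Ties are broken by preferring Gene, then Pseudogene, in a preorder pass.
    Only the subtree under ``scope_root`` (default: the whole tree) is
    labeled; leaves without an observation are ignored in the optimization.
    """
    obs = {ls.species: _LEAF_TO_ANC[ls.state] for ls in leaf_states}
    root = tree.node(scope_root) if scope_root else tree.root
    cost: dict[int, dict[str, float]] = {}

    for node in root.postorder():
        if node.is_leaf:
            if node.name in obs:
                cost[id(node)] = {s: (0 if s == obs[node.name] else INF)
                                  for s in ANC_STATES}
            else:
                cost[id(node)] = {s: 0 for s in ANC_STATES}
        else:
            cost[id(node)] = {
                s: sum(min(cost[id(c)][t] + costs[(s, t)] for t in ANC_STATES)
                       for c in node.children)
                for s in ANC_STATES}

    assigned: dict[str, str] = {}
    for node in root.preorder():
        c = cost[id(node)]
        if node.parent is None or node is root:
            best = min(ANC_STATES, key=lambda s: (c[s], ANC_STATES.index(s)))
        else:
            ps = assigned[node.parent.name]
            best = min(ANC_STATES,
                       key=lambda s: (c[s] + costs[(ps, s)],
                                      ANC_STATES.index(s)))
        assigned[node.name] = best
    return assigned


def place_events(states: dict[str, str], tree: SpeciesTree,
                 mutation_reports: Optional[dict] = None
                 ) -> tuple[Optional[str], list[EventPlacement]]:
    """Events on every branch whose child state differs from its parent's.

    Gene->Pseudogene is a pseudogenization (decorated with the mutations
    attributed to that branch), Gene->Absent and Pseudogene->Absent are gene
    losses.  The gene birth is the highest node assigned Gene.  Returns
    (birth_node, placements).
    """
    muts_by_branch: dict[tuple, list] = {}
    if mutation_reports:
        for rep in mutation_reports.values():
            for m in rep.mutations:
                if m.branch is not None:
                    bucket = muts_by_branch.setdefault(tuple(m.branch), [])
                    if not any(m2 is m for m2 in bucket):
                        bucket.append(m)

    gene_nodes = [n for n in states if states[n] == "Gene"]
    birth = None
    if gene_nodes:
        birth = min(gene_nodes, key=lambda n: tree.depth(n))

    placements: list[EventPlacement] = []
    for name, state in states.items():
        node = tree.node(name)
        if node.parent is None or node.parent.name not in states:
            continue
        parent_state = states[node.parent.name]
        if parent_state == state:
            continue
        branch = (node.parent.name, name)
        if (parent_state, state) in (("Gene", "Absent"), ("Pseudogene", "Absent")):
            placements.append(EventPlacement(branch, "gene_loss"))
        elif (parent_state, state) == ("Gene", "Pseudogene"):
            placements.append(EventPlacement(
                branch, "pseudogenization",
                supporting_mutations=muts_by_branch.get(branch, [])))
        else:
            raise ConsistencyError(
                f"forbidden transition {parent_state}->{state} on {branch}")
    placements.sort(key=lambda p: p.branch)
    return birth, placements
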