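import math

import numpy as np
import pytest

from oracles import (brute_reconcile_labels, node_splits, path_distances,
                     random_binary_tree, tree_splits)
from pseudotrace.errors import DomainError
from pseudotrace.formats_io import SequenceRecord
from pseudotrace.gene_tree import (build_nj, build_reconciled_tree,
                                   enumerate_subfamily_roots,
                                   extract_ortholog_group, missing_species,
                                   pairwise_distances, reconcile,
                                   root_gene_tree)
from pseudotrace.species_tree import SpeciesTree, TreeNode, parse_newick_node


def _rec(id_, seq, species=None):
    return SequenceRecord(id=id_, species=species or id_.split("|")[0],
                          seq=seq, kind="protein")


class TestPairwiseDistances:
    def test_identical_sequences_zero_distance(self):
        recs = [_rec(f"S{i}|g", "MKVLIEQWRA") for i in range(3)]
        for i, r in enumerate(recs):
            object.__setattr__(r, "species", f"S{i}")
        D, labels = pairwise_distances(recs)
        assert np.allclose(D, 0)

    def test_single_mismatch_closed_form(self):
        a = "MKVLIEQWRA"
        b = "MKVLIEQWRG"  # 1 of 10 differs
        recs = [_rec("A|g", a), _rec("B|g", b), _rec("C|g", a)]
        D, labels = pairwise_distances(recs)
        i, j = labels.index("A|g"), labels.index("B|g")
        assert D[i, j] == pytest.approx(-math.log(0.9))

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        recs = [_rec(f"S{i}|g", "".join(rng.choice(list(aas), 40)))
                for i in range(4)]
        D, _ = pairwise_distances(recs)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(DomainError):
            pairwise_distances([_rec("A|g", "MKV"), _rec("B|g", "MKV")])


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        t = build_nj(D, ["A", "B", "C"])
        assert sorted(t.leaf_names()) == ["A", "B", "C"]

    def test_recovers_quartet_split(self):
        # ((A:1,B:2):1,(C:3,D:1)) -> split AB|CD
        D = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        t = build_nj(D, ["A", "B", "C", "D"])
        assert node_splits(t) == {frozenset({"A", "B"})}

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovery(self, seed):
        """NJ is guaranteed to recover the generating topology on additive
        distances; checked against random trees of 4-12 taxa."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels = [f"T{i}" for i in range(n)]
        tree = random_binary_tree(rng, labels)
        dist = path_distances(tree)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = dist[frozenset((labels[i], labels[j]))]
        out = build_nj(D, labels)
        assert node_splits(out) == tree_splits(tree)

    def test_nan_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(DomainError):
            build_nj(D, ["A", "B", "C"])


class TestRootingAndReconciliation:
    def test_congruent_tree_rooted_with_zero_duplications(self, tree3):
        g = parse_newick_node("((Hsa_1:1,Ptr_1:1):1,Mus_1:2);")
        species_of = {"Hsa_1": "Hsa", "Ptr_1": "Ptr", "Mus_1": "Mus"}
        rooted = root_gene_tree(g, tree3, species_of)
        rec = reconcile(rooted, tree3, species_of)
        assert rec.duplication_count() == 0

    def test_paralog_pair_rooted_on_outgroup_edge(self, tree3):
        # ((Hsa_1,Hsa_2),Mus_1): every rooting implies >= 1 duplication;
        # rooting on the Mus edge achieves the minimum of 1
        g = parse_newick_node("((Hsa_1:1,Hsa_2:1):1,Mus_1:2);")
        species_of = {"Hsa_1": "Hsa", "Hsa_2": "Hsa", "Mus_1": "Mus"}
        rooted = root_gene_tree(g, tree3, species_of)
        rec = reconcile(rooted, tree3, species_of)
        assert rec.duplication_count() == 1
        dup = [n for n in rec.root.preorder() if n.label == "duplication"]
        assert sorted(dup[0].leaf_names()) == ["Hsa_1", "Hsa_2"]
        assert dup[0].mapping == "Hsa"

    def test_rooting_invariant_to_leaf_order(self, tree3):
        species_of = {"Hsa_1": "Hsa", "Ptr_1": "Ptr", "Mus_1": "Mus"}
        a = root_gene_tree(parse_newick_node("((Hsa_1:1,Ptr_1:1):1,Mus_1:2);"),
                           tree3, species_of)
        b = root_gene_tree(parse_newick_node("((Ptr_1:1,Hsa_1:1):1,Mus_1:2);"),
                           tree3, species_of)
        assert node_splits(a) == node_splits(b)

    def test_duplication_label_by_hand(self, tree3):
        g = parse_newick_node("((Hsa_1:1,Hsa_2:1)D:1,Mus_1:2)R;")
        rec = reconcile(g, tree3,
                        {"Hsa_1": "Hsa", "Hsa_2": "Hsa", "Mus_1": "Mus"})
        nodes = {n.name: n for n in rec.root.preorder()}
        assert nodes["D"].label == "duplication" and nodes["D"].mapping == "Hsa"
        assert nodes["R"].label == "speciation" and nodes["R"].mapping == "Eth"

    @pytest.mark.parametrize("seed", range(20))
    def test_reconciliation_matches_brute_force(self, seed, tree5):
        """Speciation/duplication labels equal an independent recomputation
        of the LCA mappings on random gene trees."""
        rng = np.random.default_rng(seed)
        species = tree5.leaf_names
        n = int(rng.integers(3, 11))
        leaf_species = [species[i] for i in rng.integers(0, len(species), n)]
        names = [f"{sp}_{i}" for i, sp in enumerate(leaf_species)]
        nodes = [TreeNode(nm, 1.0) for nm in names]
        while len(nodes) > 1:
            i = int(rng.integers(0, len(nodes)))
            a = nodes.pop(i)
            j = int(rng.integers(0, len(nodes)))
            b = nodes.pop(j)
            p = TreeNode("", 1.0)
            p.add_child(a)
            p.add_child(b)
            nodes.append(p)
        root = nodes[0]
        species_of = dict(zip(names, leaf_species))
        rec = reconcile(root, tree5, species_of)
        expected = brute_reconcile_labels(root, tree5, species_of)
        for node in rec.root.preorder():
            if not node.is_leaf:
                assert node.label == expected[id(node)]


class TestOrthologGroups:
    @pytest.fixture
    def fig1(self):
        # species tree with Hsa, Ptr, Mmu under Ctr plus Mus outgroup (Eth)
        st = SpeciesTree.from_newick(
            "(((Hsa:6,Ptr:6)Hpa:19,Mmu:25)Ctr:65,Mus:90)Eth;")
        # gene tree: duplication at Eth into two sub-families; sub-family 1
        # keeps all Catarrhini, sub-family 2 lost the Hsa copy
        g = parse_newick_node(
            "(Mus_1:3,((Hsa_1:1,(Ptr_1:1,Mmu_2:1):1):1,(Ptr_2:1,Mmu_1:1):2):1);")
        species_of = {"Mus_1": "Mus", "Hsa_1": "Hsa", "Ptr_1": "Ptr",
                      "Mmu_2": "Mmu", "Ptr_2": "Ptr", "Mmu_1": "Mmu"}
        rooted = root_gene_tree(g, st, species_of)
        return st, reconcile(rooted, st, species_of)

    def test_eutheria_group_contains_everything(self, fig1):
        st, rec = fig1
        group = extract_ortholog_group(rec, "Mmu_1", "Eth")
        assert {gid for _, gid in group.members} == \
               {"Mus_1", "Hsa_1", "Ptr_1", "Mmu_2", "Ptr_2", "Mmu_1"}
        assert missing_species(group, st, "Eth") == set()

    def test_catarrhini_group_shows_human_loss(self, fig1):
        st, rec = fig1
        group = extract_ortholog_group(rec, "Mmu_1", "Ctr")
        assert {gid for _, gid in group.members} == {"Ptr_2", "Mmu_1"}
        assert missing_species(group, st, "Ctr") == {"Hsa"}

    def test_full_tree_group_for_congruent_family(self, tree3):
        g = parse_newick_node("((Hsa_1:1,Ptr_1:1):1,Mus_1:2);")
        species_of = {"Hsa_1": "Hsa", "Ptr_1": "Ptr", "Mus_1": "Mus"}
        rec = reconcile(root_gene_tree(g, tree3, species_of), tree3, species_of)
        group = extract_ortholog_group(rec, "Hsa_1", "Eth")
        assert len(group.members) == 3

    def test_subfamily_roots_empty_without_duplication(self, tree3):
        g = parse_newick_node("((Hsa_1:1,Ptr_1:1):1,Mus_1:2);")
        species_of = {"Hsa_1": "Hsa", "Ptr_1": "Ptr", "Mus_1": "Mus"}
        rec = reconcile(root_gene_tree(g, tree3, species_of), tree3, species_of)
        assert enumerate_subfamily_roots(rec, "Hsa_1", "Eth") == []

    def test_subfamily_root_after_duplication(self, fig1):
        st, rec = fig1
        roots = enumerate_subfamily_roots(rec, "Mmu_1", "Eth")
        assert len(roots) >= 1
        assert all(n.label == "speciation" for n in roots)
        assert all(n.parent.label == "duplication" for n in roots)


class TestEndToEndTree:
    def test_build_reconciled_tree_congruent_family(self, tree5):
        """A single-copy family evolved along the species tree reconstructs
        with zero duplications and a full Eutheria ortholog group."""
        rng = np.random.default_rng(1)
        base = list("MKVLIEQWRAGDNSTYFPHC" * 4)
        seqs = {}

        def evolve(node, seq):
            seq = seq.copy()
            n_sub = max(1, int(0.05 * (node.length or 0)))
            for pos in rng.integers(0, len(seq), n_sub):
                seq[pos] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
            if node.is_leaf:
                seqs[node.name] = "".join(seq)
            for c in node.children:
                evolve(c, seq)

        for c in tree5.root.children:
            evolve(c, base)
        recs = [_rec(f"{sp}|g1", seqs[sp], sp) for sp in sorted(seqs)]
        rec = build_reconciled_tree(recs, tree5)
        assert rec.duplication_count() == 0
        group = extract_ortholog_group(rec, recs[0].id, "Eth")
        assert len(group.members) == len(tree5.leaf_names)
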