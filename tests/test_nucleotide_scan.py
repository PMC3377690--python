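import numpy as np
import pytest

from oracles import brute_sankoff_min_cost
from pseudotrace.alignment import back_translate
from pseudotrace.errors import InsufficientDataError
from pseudotrace.formats_io import SequenceRecord
from pseudotrace.nucleotide_scan import (CandidateLocus, CompactedAlignment,
                                         KnownOrtholog, build_guided_alignment,
                                         classify_sequence, MutationReport,
                                         Mutation, reconstruct_ancestors,
                                         scan_lineage, scan_pair,
                                         select_reconstruction_set,
                                         tn93_distance)
from pseudotrace.species_tree import SpeciesTree, TreeNode, parse_newick_node


def _rng_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_gene(rng, exon_lens=(30, 45, 30), intron_lens=(40, 40)):
    n_aa = sum(exon_lens) // 3 - 2
    body = "".join("ACDEFGHIKLNPQRSVWY"[i]
                   for i in rng.integers(0, 18, n_aa))
    cds = "ATG" + back_translate(body) + "TAA"
    exons, pos = [], 0
    for l in exon_lens:
        exons.append(cds[pos:pos + l])
        pos += l
    introns = ["GT" + _rng_dna(rng, l - 4) + "AG" for l in intron_lens]
    return exons, introns


def assemble(exons, introns, rng, flank=60):
    parts = []
    for i, ex in enumerate(exons):
        parts.append(ex)
        if i < len(introns):
            parts.append(introns[i])
    gene = "".join(parts)
    left, right = _rng_dna(rng, flank), _rng_dna(rng, flank)
    locus = left + gene + right
    exons_local, pos = [], len(left)
    for i, ex in enumerate(exons):
        exons_local.append((pos, pos + len(ex)))
        pos += len(ex)
        if i < len(introns):
            pos += len(introns[i])
    return locus, tuple(exons_local)


def _dna(name, seq):
    return SequenceRecord(id=name, species=name, seq=seq, kind="dna")


@pytest.fixture
def gene_fixture():
    rng = np.random.default_rng(42)
    exons, introns = make_gene(rng)
    locus, exons_local = assemble(exons, introns, rng)
    return rng, exons, introns, locus, exons_local


class TestGuidedAlignment:
    def test_identical_sequences_no_gap_columns(self, gene_fixture):
        _, exons, introns, locus, exons_local = gene_fixture
        seqs = [_dna("ref", locus), _dna("a", locus), _dna("b", locus)]
        aln = build_guided_alignment(seqs, "ref", exons_local, flank=20)
        assert all("-" not in row for row in aln.rows.values())
        # 3 exons: 2 outer flanks + 2 flanks per junction = 6 flank segments
        expected = sum(len(e) for e in exons) + 6 * 20
        assert aln.n_columns == expected

    def test_intronic_insert_removed_by_compaction(self, gene_fixture):
        rng, exons, introns, locus, exons_local = gene_fixture
        fat_introns = list(introns)
        mid = len(introns[0]) // 2
        fat_introns[0] = (introns[0][:mid] + _rng_dna(rng, 300)
                          + introns[0][mid:])
        parts = []
        for i, ex in enumerate(exons):
            parts.append(ex)
            if i < len(fat_introns):
                parts.append(fat_introns[i])
        fat_locus = "".join(parts)
        seqs = [_dna("ref", locus), _dna("fat", fat_locus), _dna("b", locus)]
        aln = build_guided_alignment(seqs, "ref", exons_local, flank=10)
        # compacted width is bounded by the reference exon+flank footprint,
        # so the 300 nt insert cannot survive
        assert aln.n_columns <= sum(len(e) for e in exons) + 2 * 2 * 10 + 20

    def test_projection_on_gapfree_rows_matches_reference_coords(self,
                                                                 gene_fixture):
        _, exons, introns, locus, exons_local = gene_fixture
        seqs = [_dna("ref", locus), _dna("a", locus), _dna("b", locus)]
        aln = build_guided_alignment(seqs, "ref", exons_local, flank=20)
        for k, cols in enumerate(aln.exon_columns):
            ref_seq = "".join(aln.rows["ref"][c] for c in cols)
            assert ref_seq == exons[k]


class TestReconstructAncestors:
    def _aln_from_rows(self, rows):
        return CompactedAlignment(rows=rows, reference=next(iter(rows)),
                                  exon_columns=[], exon_intervals=[],
                                  donor_columns=[], acceptor_columns=[],
                                  column_map={})

    def _guide(self, newick):
        return parse_newick_node(newick)

    def test_identical_rows_identical_ancestors(self):
        rows = {n: "ACGTACGT" for n in "abcd"}
        guide = self._guide("((a:1,b:1)x:1,(c:1,d:1)y:1)r;")
        anc = reconstruct_ancestors(self._aln_from_rows(rows), guide)
        assert set(anc) == {"x", "y", "r"}
        assert all(v == "ACGTACGT" for v in anc.values())

    def test_single_variant_column_majority(self):
        rows = {"a": "ACGT", "b": "ACGT", "c": "ACGT", "d": "ACTT"}
        guide = self._guide("((a:1,b:1)x:1,(c:1,d:1)y:1)r;")
        anc = reconstruct_ancestors(self._aln_from_rows(rows), guide)
        assert anc["r"] == "ACGT" and anc["x"] == "ACGT" and anc["y"] == "ACGT"

    @pytest.mark.parametrize("seed", range(6))
    def test_parsimony_cost_matches_brute_force(self, seed):
        """Total tree cost of the reconstruction equals the exhaustive
        minimum over all ancestral assignments (<=5 taxa, <=15 columns)."""
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(3, 6))
        ncol = int(rng.integers(4, 16))
        names = [f"t{i}" for i in range(n_taxa)]
        rows = {n: "".join("ACGT-"[i] for i in rng.integers(0, 5, ncol))
                for n in names}
        nodes = [TreeNode(n, 1.0) for n in names]
        k = 0
        while len(nodes) > 1:
            i = int(rng.integers(0, len(nodes)))
            a = nodes.pop(i)
            j = int(rng.integers(0, len(nodes)))
            b = nodes.pop(j)
            k += 1
            p = TreeNode(f"I{k}", 1.0)
            p.add_child(a)
            p.add_child(b)
            nodes.append(p)
        guide = nodes[0]
        anc = reconstruct_ancestors(self._aln_from_rows(rows), guide)

        def col_cost(j):
            def cost(p, c):
                return 0.0 if p == c else 1.0
            total = 0.0
            for node in guide.preorder():
                if node.parent is None:
                    continue
                ps = (anc[node.parent.name][j] if not node.parent.is_leaf
                      else rows[node.parent.name][j])
                cs = (rows[node.name][j] if node.is_leaf
                      else anc[node.name][j])
                total += cost(ps, cs)
            obs = {n: rows[n][j] for n in names}
            want = brute_sankoff_min_cost(guide, obs, "ACGT-", cost)
            return total, want

        for j in range(ncol):
            got, want = col_cost(j)
            assert got == want, f"column {j}"


class TestScanPair:
    def _aligned(self, ref_locus, desc_locus, exons_local):
        seqs = [_dna("ref", ref_locus), _dna("desc", desc_locus),
                _dna("out", ref_locus)]
        return build_guided_alignment(seqs, "ref", exons_local, flank=20)

    def test_identity_yields_no_mutation(self, gene_fixture):
        _, exons, introns, locus, exons_local = gene_fixture
        aln = self._aligned(locus, locus, exons_local)
        assert scan_pair(aln.rows["desc"], aln.rows["ref"], aln) == []

    def test_planted_nonsense_exact_position(self, gene_fixture):
        _, exons, introns, locus, exons_local = gene_fixture
        s, e = exons_local[1]
        codon = 5
        desc = (locus[:s + 3 * codon] + "TAA" + locus[s + 3 * codon + 3:])
        aln = self._aligned(locus, desc, exons_local)
        muts = scan_pair(aln.rows["desc"], aln.rows["ref"], aln)
        assert [(m.kind, m.exon_index, m.position) for m in muts] == \
               [("nonsense", 1, 5)]

    def test_deletion_frameshift_and_splice_change(self, gene_fixture):
        _, exons, introns, locus, exons_local = gene_fixture
        s0, e0 = exons_local[0]
        # 2 nt deletion inside exon 0 and donor GT -> GC at junction 0;
        # after the deletion the donor dinucleotide sits at [e0-2, e0)
        desc = locus[:s0 + 12] + locus[s0 + 14:]
        desc = desc[:e0 - 1] + "C" + desc[e0:]
        aln = self._aligned(locus, desc, exons_local)
        muts = scan_pair(aln.rows["desc"], aln.rows["ref"], aln)
        kinds = {(m.kind, m.exon_index) for m in muts}
        assert ("deletion", 0) in kinds
        assert ("frameshift", 0) in kinds
        assert ("splice_donor", 0) in kinds
        deletion = next(m for m in muts if m.kind == "deletion")
        assert deletion.detail == "2" and deletion.position == 12

    def test_start_and_stop_loss(self, gene_fixture):
        _, exons, introns, locus, exons_local = gene_fixture
        s0, _ = exons_local[0]
        sl, el = exons_local[-1]
        desc = locus[:s0] + "ATA" + locus[s0 + 3:]          # ATG -> ATA
        desc = desc[:el - 3] + "TCA" + desc[el:]            # TAA -> TCA
        aln = self._aligned(locus, desc, exons_local)
        kinds = {m.kind for m in
                 scan_pair(aln.rows["desc"], aln.rows["ref"], aln)}
        assert kinds == {"start_loss", "stop_loss"}

    def test_exon_loss(self, gene_fixture):
        _, exons, introns, locus, exons_local = gene_fixture
        s, e = exons_local[1]
        desc = locus[:s] + locus[e:]
        aln = self._aligned(locus, desc, exons_local)
        muts = scan_pair(aln.rows["desc"], aln.rows["ref"], aln)
        assert any(m.kind == "exon_loss" and m.exon_index == 1 for m in muts)


class TestScanLineage:
    def _setup(self, gene_fixture, mutate):
        _, exons, introns, locus, exons_local = gene_fixture
        st = SpeciesTree.from_newick(
            "(((Hsa:6,Ptr:6)Hpa:19,Mmu:25)Ctr:65,Mus:90)Eth;")
        loci = {sp: locus for sp in ("Hsa", "Ptr", "Mmu", "Mus")}
        loci.update(mutate(locus, exons_local))
        seqs = [_dna(sp, loci[sp]) for sp in ("Mus", "Mmu", "Ptr", "Hsa")]
        aln = build_guided_alignment(seqs, "Mus", exons_local, flank=20)
        from pseudotrace.orchestrator import restrict_species_tree
        guide = restrict_species_tree(st, ["Hsa", "Ptr", "Mmu", "Mus"])
        anc = reconstruct_ancestors(aln, guide)
        return aln, anc, guide

    def test_ancestral_mutation_on_internal_branch(self, gene_fixture):
        def mutate(locus, exons_local):
            s, _ = exons_local[1]
            broken = locus[:s + 15] + "TAA" + locus[s + 18:]
            return {"Hsa": broken, "Ptr": broken}

        aln, anc, guide = self._setup(gene_fixture, mutate)
        reports = scan_lineage(aln, anc, guide, ["Hsa", "Ptr"])
        hsa_nonsense = [m for m in reports["Hsa"].mutations
                        if m.kind == "nonsense"]
        assert len(hsa_nonsense) == 1
        assert hsa_nonsense[0].branch == ("Ctr", "Hpa")
        # reported once: the same Mutation object serves both targets
        assert [m for m in reports["Ptr"].mutations
                if m.kind == "nonsense"][0] is hsa_nonsense[0]

    def test_independent_terminal_mutations(self, gene_fixture):
        def mutate(locus, exons_local):
            s, _ = exons_local[1]
            return {"Hsa": locus[:s + 15] + "TAA" + locus[s + 18:],
                    "Mmu": locus[:s + 24] + "TGA" + locus[s + 27:]}

        aln, anc, guide = self._setup(gene_fixture, mutate)
        reports = scan_lineage(aln, anc, guide, ["Hsa", "Mmu"])
        hsa = [m for m in reports["Hsa"].mutations if m.kind == "nonsense"]
        mmu = [m for m in reports["Mmu"].mutations if m.kind == "nonsense"]
        assert len(hsa) == 1 and hsa[0].branch == ("Hpa", "Hsa")
        assert len(mmu) == 1 and mmu[0].branch == ("Ctr", "Mmu")

    def test_clean_fixture_all_reports_empty(self, gene_fixture):
        aln, anc, guide = self._setup(gene_fixture, lambda l, e: {})
        reports = scan_lineage(aln, anc, guide, ["Hsa", "Ptr", "Mmu", "Mus"])
        assert all(r.mutations == [] for r in reports.values())


class TestClassify:
    def test_rules(self):
        assert classify_sequence(MutationReport("x", [])) == "intact"
        assert classify_sequence(MutationReport(
            "x", [Mutation("nonsense", 0, 1)])) == "pseudogene"
        assert classify_sequence(MutationReport(
            "x", [Mutation("deletion", 0, 1, "3")])) == "intact"
        assert classify_sequence(MutationReport(
            "x", [Mutation("deletion", 0, 1, "2"),
                  Mutation("frameshift", 0, 1, "2")])) == "pseudogene"

    def test_monotone_adding_mutations(self):
        base = [Mutation("insertion", 0, 1, "3")]
        assert classify_sequence(MutationReport("x", base)) == "intact"
        worse = base + [Mutation("splice_donor", 0, 0, "GC")]
        assert classify_sequence(MutationReport("x", worse)) == "pseudogene"


class TestSelectReconstructionSet:
    PROT = "MKVLIEQWRAGDNSTYFPHC" * 3

    def _known(self, sp, prot):
        rec = SequenceRecord(f"{sp}|g1", sp, prot, "protein")
        locus = SequenceRecord(sp, sp, back_translate(prot), "dna")
        return KnownOrtholog(sp, rec, locus, ((0, len(prot) * 3),))

    def test_one_per_species_keeps_more_similar(self):
        ref = SequenceRecord("Ptr|g1", "Ptr", self.PROT, "protein")
        good = self._known("Mus", self.PROT)
        worse = KnownOrtholog("Mus", SequenceRecord(
            "Mus|g2", "Mus", self.PROT[:40] + "W" * 20, "protein"),
            good.locus, good.exons_local)
        cand = CandidateLocus("Hsa", SequenceRecord("Hsa", "Hsa", "ATG" * 30,
                                                    "dna"), 80.0)
        knowns, cands = select_reconstruction_set(
            [worse, good, self._known("Mmu", self.PROT)], [cand], ref)
        mus = [k for k in knowns if k.species == "Mus"]
        assert len(mus) == 1 and mus[0].protein.id == "Mus|g1"

    def test_divergent_known_dropped(self):
        ref = SequenceRecord("Ptr|g1", "Ptr", self.PROT, "protein")
        alien = self._known("Mdo", "WHWHWHWHWHWHWHWH")
        cand = CandidateLocus("Hsa", SequenceRecord("Hsa", "Hsa", "ATG" * 30,
                                                    "dna"), 80.0)
        knowns, _ = select_reconstruction_set(
            [alien, self._known("Mus", self.PROT),
             self._known("Mmu", self.PROT)],
            [cand], ref, max_divergence_pct=50)
        assert all(k.species != "Mdo" for k in knowns)

    def test_too_few_survivors_is_insufficient(self):
        ref = SequenceRecord("Ptr|g1", "Ptr", self.PROT, "protein")
        alien = self._known("Mdo", "WHWHWHWHWHWHWHWH")
        cand = CandidateLocus("Hsa", SequenceRecord("Hsa", "Hsa", "ATG" * 30,
                                                    "dna"), 80.0)
        with pytest.raises(InsufficientDataError):
            select_reconstruction_set([alien, self._known("Mus", self.PROT)],
                                      [cand], ref, max_divergence_pct=50)


class TestTn93:
    def test_zero_for_identical(self):
        assert tn93_distance("ACGTACGTAC", "ACGTACGTAC") == 0

    def test_symmetric_and_increasing(self):
        rng = np.random.default_rng(0)
        a = _rng_dna(rng, 400)
        b1 = list(a)
        b2 = list(a)
        for pos in rng.integers(0, 400, 10):
            b1[pos] = "A" if a[pos] != "A" else "C"
        for pos in rng.integers(0, 400, 60):
            b2[pos] = "A" if a[pos] != "A" else "C"
        d1 = tn93_distance(a, "".join(b1))
        d2 = tn93_distance(a, "".join(b2))
        assert 0 < d1 < d2
        assert tn93_distance("".join(b2), a) == pytest.approx(d2)
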