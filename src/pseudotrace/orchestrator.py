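"""The study driver: detection, per-species rescue, synthesis.

Phase 1 builds a gene phylogeny from proteome homologs of the query,
reconciles it with the species tree and reads off the ortholog group
established at the chosen ancestor; species of the study set with no member
in the group are loss candidates.  Phase 2 (complete mode) re-examines each
candidate genome: a translated search recovers candidate loci, orthology is
re-checked phylogenetically, an annotated gene at the locus ends the study
for that species (Present), and otherwise the recovered sequence is judged
at protein level (conservation test) or at nucleotide level (ancestral
reconstruction + mutation scan) to separate Saved genes from Pseudogenes.
Phase 3 synthesizes per-species verdicts into branch-placed events by
parsimony and writes the reports.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import event_synthesis, gene_tree, homology_search, nucleotide_scan
from .errors import (DomainError, InsufficientDataError, LookupError_,
                     PseudotraceError)
from .formats_io import (ExonAnnotation, RunConfig, SequenceRecord,
                         write_annotated_tree, write_report_json)
from .gene_prediction import (PredictParams, find_annotated_gene_at_locus,
                              predict_protein)
from .homology_search import SearchParams, chain_hits, extract_locus, translated_search
from .nucleotide_scan import (CandidateLocus, KnownOrtholog,
                              build_guided_alignment, classify_sequence,
                              reconstruct_ancestors, scan_lineage,
                              select_reconstruction_set)
from .protein_tests import (conservation_test, global_identity,
                            select_known_pair, signal_gate)
from .species_tree import SpeciesTree, TreeNode
from .alignment import reverse_complement

__all__ = ["StudyInputs", "StudyReport", "run_study", "run_batch",
           "restrict_species_tree", "write_outputs"]


@dataclass
class StudyInputs:
    """Everything a study reads: tree, query, proteomes, genomes, exons."""

    species_tree: SpeciesTree
    query: SequenceRecord
    proteomes: dict            # species -> list[SequenceRecord]
    genomes: dict = field(default_factory=dict)   # species -> list[SequenceRecord]
    annotations: list = field(default_factory=list)

    @classmethod
    def from_simulated(cls, study, query_species: Optional[str] = None):
        return cls(species_tree=study.params.tree,
                   query=study.query_record(query_species),
                   proteomes={sp: list(rs) for sp, rs in study.proteomes.items()},
                   genomes={sp: [rec] for sp, rec in study.genomes.items()},
                   annotations=list(study.annotations))


@dataclass
class StudyReport:
    query: str
    ancestor: str
    mode: str
    verdicts: dict = field(default_factory=dict)   # species -> verdict
    evidence: dict = field(default_factory=dict)   # species -> dict
    events: list = field(default_factory=list)     # EventPlacement
    birth_node: Optional[str] = None
    warnings: list = field(default_factory=list)
    subfamilies: list = field(default_factory=list)  # optional lineage scan

    @property
    def leaf_states(self) -> dict:
        return {sp: v for sp, v in self.verdicts.items() if v != "Unresolved"}

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "ancestor": self.ancestor,
            "mode": self.mode,
            "verdicts": dict(sorted(self.verdicts.items())),
            "evidence": {sp: self.evidence.get(sp, {})
                         for sp in sorted(self.verdicts)},
            "events": [
                {"branch": list(ev.branch), "event": ev.event,
                 "mutations": [
                     {"kind": m.kind, "exon": m.exon_index,
                      "position": m.position, "detail": m.detail,
                      "branch": list(m.branch) if m.branch else None}
                     for m in ev.supporting_mutations]}
                for ev in self.events],
            "birth_node": self.birth_node,
            "warnings": sorted(self.warnings),
            "subfamilies": self.subfamilies,
        }


# ---------------------------------------------------------------------------
# Species-tree restriction (guide tree for the reconstruction step)

def restrict_species_tree(tree: SpeciesTree, taxa: Sequence[str]) -> TreeNode:
    """Induced subtree on a leaf subset, suppressing degree-2 nodes.

    Retained internal nodes keep their species-tree names, so branches of the
    restricted tree can be mapped back to the full tree by child name.
    """
    taxa = set(taxa)
    unknown = taxa - set(tree.leaf_names)
    if unknown:
        raise LookupError_(f"taxa not in species tree: {sorted(unknown)}")
    if len(taxa) < 2:
        raise DomainError("restriction needs >= 2 taxa")

    def rec(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.name in taxa:
                return TreeNode(node.name, node.length or 0.0)
            return None
        kept = [rec(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        new = TreeNode(node.name, node.length or 0.0)
        for k in kept:
            new.add_child(k)
        return new

    out = rec(tree.root)
    out.length = None
    return out


# ---------------------------------------------------------------------------

def _gather_homologs(inputs: StudyInputs, config: RunConfig) -> list[SequenceRecord]:
    """Phase-1 family assembly: top N proteome entries per species by
    identity to the query, above the configured identity floor."""
    min_ident = config.thresholds["phase1_min_identity_pct"]
    top_n = int(config.thresholds["phase1_top_n"])
    family = [inputs.query]
    seen = {inputs.query.id}
    for sp in sorted(inputs.proteomes):
        scored = []
        for rec in inputs.proteomes[sp]:
            if rec.id in seen or rec.id in config.excluded_gene_ids:
                continue
            ident = global_identity(rec.seq, inputs.query.seq).identity_pct
            if ident >= min_ident:
                scored.append((-ident, rec.id, rec))
        for _, _, rec in sorted(scored)[:top_n]:
            family.append(rec)
            seen.add(rec.id)
    return family


def _phase1(inputs: StudyInputs, config: RunConfig):
    """Gene tree + ortholog group + missing species."""
    warnings = []
    family = _gather_homologs(inputs, config)
    group_records = {r.id: r for r in family}
    rtree = None
    if len(family) >= 3:
        rtree = gene_tree.build_reconciled_tree(family, inputs.species_tree)
        group = gene_tree.extract_ortholog_group(rtree, inputs.query.id,
                                                 config.ancestor)
        if not group.members:
            warnings.append("no speciation node at or under the ancestor; "
                            "falling back to the full homolog set")
            group = gene_tree.OrthologGroup(
                {(r.species, r.id) for r in family}, None, config.ancestor)
    else:
        warnings.append("fewer than 3 homologs; skipping gene-tree phase")
        group = gene_tree.OrthologGroup(
            {(r.species, r.id) for r in family}, None, config.ancestor)
    missing = gene_tree.missing_species(group, inputs.species_tree,
                                        config.ancestor)
    members = {gid: group_records[gid] for _, gid in group.members
               if gid in group_records}
    subfamilies = []
    if config.scan_subfamilies and rtree is not None:
        # sub-family establishment points: speciation nodes following a
        # duplication on the query-to-root path, each scanned for its own
        # lineage-specific absences
        for node in gene_tree.enumerate_subfamily_roots(
                rtree, inputs.query.id, config.ancestor):
            sub = gene_tree.OrthologGroup(
                {(rtree.species_of[l.name], l.name) for l in node.leaves()},
                node, node.mapping)
            subfamilies.append({
                "mapped_ancestor": node.mapping,
                "members": sorted(gid for _, gid in sub.members),
                "missing_species": sorted(gene_tree.missing_species(
                    sub, inputs.species_tree, node.mapping))})
    return group, members, missing, warnings, subfamilies


def _closest_reference(inputs: StudyInputs, members: dict, species: str
                       ) -> SequenceRecord:
    """Group ortholog of the species with the smallest divergence time."""
    tree = inputs.species_tree
    best = min(members.values(),
               key=lambda r: (tree.divergence_time(species, r.species)
                              if r.species != species else float("inf"),
                              r.id))
    return best


def _orthology_check(hit_protein: str, members: dict, inputs: StudyInputs,
                     species: str, reference: SequenceRecord,
                     min_identity_pct: float = 50.0) -> bool:
    """Phylogenetic orthology test of a recovered sequence.

    The hit joins a gene tree with the group proteins; it is accepted when
    its LCA with at least one group member is a speciation node (it pairs
    with a member by descent, not duplication).  When the tree carries no
    signal — near-identical sequences make every topology and hence every
    duplication label arbitrary — a hit this similar to the reference cannot
    be rejected as non-orthologous, so high identity to the reference is
    accepted directly.
    """
    clean = hit_protein.replace("*", "X")
    if len(members) < 2 or len(clean) < 10:
        return True  # too little signal for a tree: accept, flag upstream
    if global_identity(clean, reference.seq).identity_pct >= min_identity_pct:
        return True
    records = list(members.values())
    hit_rec = SequenceRecord(id=f"{species}|hit", species=species,
                             seq=clean, kind="protein")
    try:
        rtree = gene_tree.build_reconciled_tree(records + [hit_rec],
                                                inputs.species_tree)
    except (DomainError, PseudotraceError):
        return True
    leaf = rtree.leaf(hit_rec.id)
    for member_id in members:
        lca = _gene_tree_lca(rtree, leaf, member_id)
        if lca is not None and lca.label == "speciation":
            return True
    return False


def _gene_tree_lca(rtree, leaf, other_name):
    try:
        other = rtree.leaf(other_name)
    except PseudotraceError:
        return None
    anc = set()
    n = leaf
    while n is not None:
        anc.add(id(n))
        n = n.parent
    n = other
    while n is not None:
        if id(n) in anc:
            return n
        n = n.parent
    return None


def _known_orthologs(inputs: StudyInputs, members: dict,
                     flank: int = 100) -> list[KnownOrtholog]:
    """Gene-region loci (with introns and a small flank) of annotated
    group members, in transcript orientation."""
    out = []
    ann_by_gene = {a.gene_id: a for a in inputs.annotations}
    for gid, rec in sorted(members.items()):
        ann = ann_by_gene.get(gid)
        if ann is None:
            continue
        chroms = inputs.genomes.get(ann.species, [])
        chrom = next((c for c in chroms if c.id == ann.chrom), None)
        if chrom is None:
            continue
        lo, hi = ann.span
        start = max(0, lo - flank)
        end = min(len(chrom.seq), hi + flank)
        seq = chrom.seq[start:end]
        if ann.strand == "+":
            exons_local = tuple((s - start, e - start) for s, e in ann.exons)
        else:
            seq = reverse_complement(seq)
            exons_local = tuple((end - e, end - s) for s, e in ann.exons)
        out.append(KnownOrtholog(species=ann.species, protein=rec,
                                 locus=SequenceRecord(id=ann.species,
                                                      species=ann.species,
                                                      seq=seq, kind="dna"),
                                 exons_local=exons_local))
    return out


def _study_candidate(inputs: StudyInputs, config: RunConfig, species: str,
                     members: dict, report: StudyReport) -> Optional[dict]:
    """Phase-2 study of one candidate species.

    Sets the species verdict in place, except for candidates that qualify
    for the nucleotide-level analysis: those are returned as pending
    records, because all recovered orthologous sequences of the study enter
    one joint reconstruction at the rendezvous.
    """
    th = config.thresholds
    ev: dict = {}
    report.evidence[species] = ev
    genome = inputs.genomes.get(species)
    if not genome:
        report.verdicts[species] = "Unresolved"
        report.warnings.append(f"{species}: no genome available")
        return None
    reference = _closest_reference(inputs, members, species)
    ev["reference"] = reference.id
    params = SearchParams(seed_k=int(th["search_seed_k"]),
                          min_score=th["search_min_score"],
                          max_gap=int(th["chain_max_gap_nt"]))
    hits = translated_search(reference, genome, params)
    ev["n_hits"] = len(hits)
    if not hits:
        report.verdicts[species] = "Lost"
        ev["conclusion"] = "no translated-search hit"
        return None
    chains = chain_hits(hits, params)
    cap = int(th["candidate_cap"])
    for rank, chain in enumerate(chains[:cap]):
        # a similar gene already described at this location means no loss,
        # even when the gene phylogeny had eliminated it
        annotated = find_annotated_gene_at_locus(
            inputs.annotations, species, chain.chrom, chain.genome_span,
            excluded=config.excluded_gene_ids)
        if annotated is not None:
            report.verdicts[species] = "Present"
            ev["annotated_gene"] = annotated
            ev["conclusion"] = "already annotated at this locus"
            return None
        if not _orthology_check(chain.concatenated_protein, members, inputs,
                                species, reference,
                                th["test1_similarity_pct"]):
            continue
        ev["chain"] = {"rank": rank, "score": chain.total_score,
                       "chrom": chain.chrom, "strand": chain.strand,
                       "span": list(chain.genome_span)}
        locus = extract_locus(genome, chain, flank=int(th["locus_flank_nt"]))
        prediction = predict_protein(
            locus, reference,
            PredictParams(min_score_frac=th["predict_min_score_frac"]))
        hit_protein = chain.concatenated_protein.replace("*", "X")
        pred_protein = prediction.protein if prediction else None
        if prediction:
            ev["prediction"] = {"length": len(prediction.protein),
                                "n_exons": len(prediction.exons),
                                "score": prediction.score}
        level = signal_gate(hit_protein, pred_protein, reference.seq,
                            similarity_pct=th["test1_similarity_pct"],
                            length_pct=th["test1_length_pct"])
        ev["signal_gate"] = level
        if level == "nucleotide_level":
            sim = global_identity(hit_protein, reference.seq).identity_pct
            # the reconstruction uses a tight locus (hit span + short flank):
            # long intergenic tails only invite alignment artifacts there
            tight = extract_locus(genome, chain, flank=200)
            return {"species": species, "reference": reference,
                    "chain": chain, "locus": tight, "similarity": sim,
                    "fallback_protein": pred_protein or hit_protein}
        _protein_verdict(inputs, species, members, reference,
                         pred_protein or hit_protein, ev, report)
        return None
    report.verdicts[species] = "Lost"
    ev["conclusion"] = "no candidate passed the orthology check"
    return None


def _protein_verdict(inputs, species, members, reference, candidate_protein,
                     ev, report) -> None:
    cand = SequenceRecord(id=f"{species}|candidate", species=species,
                          seq=candidate_protein.replace("*", "X"),
                          kind="protein")
    try:
        inp = select_known_pair(cand, list(members.values()),
                                inputs.species_tree)
    except InsufficientDataError:
        report.verdicts[species] = "Unresolved"
        report.warnings.append(f"{species}: too few knowns for test 2")
        return
    verdict = conservation_test(inp)
    ev["test2"] = {"mode": inp.mode, "D1": inp.d1, "D2": inp.d2,
                   "Value1": round(inp.value1, 3), "Value2": round(inp.value2, 3),
                   "threshold": (round(inp.d2 * inp.value2 / inp.d1, 3)
                                 if inp.mode == "same_lca" else None),
                   "verdict": verdict}
    if verdict == "putative_gene":
        report.verdicts[species] = "Saved"
        ev["conclusion"] = "conservation consistent with divergence (test 2)"
    else:
        report.verdicts[species] = "Pseudogene"
        ev["conclusion"] = "conservation below divergence expectation (test 2)"
        ev["test2_failure_flag"] = True


def _nucleotide_phase(inputs, config, members, pending, report) -> None:
    """Joint nucleotide-level analysis of all pending candidates.

    All recovered orthologous loci and the not-too-divergent known loci are
    reconstructed together, so a mutation shared by sister candidates is
    found once, on their common ancestral branch.  On any failure the
    affected candidates fall back to the protein-level verdict.
    """
    th = config.thresholds
    tree = inputs.species_tree

    def fallback(subset, reason):
        report.warnings.append(
            f"nucleotide analysis fell back to protein level ({reason})")
        for p in subset:
            _protein_verdict(inputs, p["species"], members, p["reference"],
                             p["fallback_protein"],
                             report.evidence[p["species"]], report)

    knowns = _known_orthologs(inputs, members)
    candidates = [CandidateLocus(p["species"], p["locus"].record,
                                 p["similarity"]) for p in pending]
    try:
        kept_knowns, kept_cands = select_reconstruction_set(
            knowns, candidates, inputs.query,
            max_divergence_pct=th["test3_max_divergence_pct"])
    except (InsufficientDataError, DomainError) as exc:
        fallback(pending, str(exc))
        return
    cand_species = [c.species for c in kept_cands]
    ref_known = min(kept_knowns,
                    key=lambda k: (sum(tree.divergence_time(sp, k.species)
                                       for sp in cand_species
                                       if sp != k.species), k.species))
    seqs = [SequenceRecord(id=kn.species, species=kn.species,
                           seq=kn.locus.seq, kind="dna")
            for kn in kept_knowns]
    seqs += [SequenceRecord(id=c.species, species=c.species,
                            seq=c.locus.seq, kind="dna")
             for c in kept_cands]
    try:
        aln = build_guided_alignment(seqs, ref_known.species,
                                     ref_known.exons_local,
                                     flank=int(th["compaction_flank_nt"]))
    except (PseudotraceError, DomainError) as exc:
        fallback(pending, str(exc))
        return
    taxa = [s.id for s in seqs]
    if config.force_species_tree:
        guide = restrict_species_tree(tree, taxa)
    else:
        guide = _nj_guide(aln, taxa)
    ancestors = reconstruct_ancestors(aln, guide)
    reports = scan_lineage(aln, ancestors, guide, cand_species)

    # attribute mutations to species-tree branches (by child node name);
    # on the restricted guide a child node keeps its species-tree name
    seen = set()
    for rep in reports.values():
        for m in rep.mutations:
            if id(m) in seen:
                continue
            seen.add(id(m))
            child = m.branch[1]
            node = tree.node(child)
            if node.parent is not None:
                m.branch = (node.parent.name, child)

    by_species = {p["species"]: p for p in pending}
    for sp in cand_species:
        rep = reports[sp]
        ev = report.evidence[sp]
        if rep.low_confidence_exons:
            report.warnings.append(
                f"{sp}: low-confidence projection for exons "
                f"{rep.low_confidence_exons}")
        ev["scan"] = {"n_mutations": len(rep.mutations),
                      "mutations": [
                          {"kind": m.kind, "exon": m.exon_index,
                           "position": m.position, "detail": m.detail,
                           "branch": list(m.branch)}
                          for m in rep.mutations]}
        ev["mutation_report"] = rep
        if classify_sequence(rep) == "pseudogene":
            report.verdicts[sp] = "Pseudogene"
            ev["conclusion"] = "disabling mutations found at nucleotide level"
        else:
            report.verdicts[sp] = "Saved"
            ev["conclusion"] = "no degenerate mutation at nucleotide level"
    leftovers = [p for p in pending if p["species"] not in cand_species]
    if leftovers:
        fallback(leftovers, "dropped from the reconstruction set")


def run_study(config: RunConfig, inputs: StudyInputs) -> StudyReport:
    """Execute one full study and return its report."""
    st = inputs.species_tree
    if config.ancestor not in st:
        raise LookupError_(f"ancestor {config.ancestor!r} not in species tree")
    if inputs.query.species not in st:
        raise LookupError_(
            f"query species {inputs.query.species!r} not in species tree")
    if config.mode == "complete" and not inputs.genomes:
        raise DomainError("complete mode requires genome sequences")

    report = StudyReport(query=inputs.query.id, ancestor=config.ancestor,
                         mode=config.mode)
    group, members, missing, warns, subfamilies = _phase1(inputs, config)
    report.warnings.extend(warns)
    if subfamilies:
        report.subfamilies = subfamilies
    scope = st.species_under(config.ancestor)
    for sp in sorted(scope - missing):
        report.verdicts[sp] = "Present"
        report.evidence[sp] = {"conclusion": "ortholog in the gene phylogeny"}

    if config.mode == "simple":
        presence = {sp: sp not in missing for sp in sorted(scope)}
        try:
            birth, losses = event_synthesis.dollo_losses(presence, st)
        except DomainError:
            birth, losses = None, []
        report.birth_node = birth
        for sp in sorted(missing):
            report.verdicts[sp] = "Lost"
            report.evidence[sp] = {"conclusion": "absent from the phylogeny"}
        report.events = [event_synthesis.EventPlacement(b, "gene_loss")
                         for b in losses]
        return report

    pending = []
    for sp in sorted(missing):
        try:
            p = _study_candidate(inputs, config, sp, members, report)
            if p is not None:
                pending.append(p)
        except PseudotraceError as exc:
            report.verdicts[sp] = "Unresolved"
            report.warnings.append(f"{sp}: {exc}")
    if pending:
        try:
            _nucleotide_phase(inputs, config, members, pending, report)
        except PseudotraceError as exc:
            for p in pending:
                if p["species"] not in report.verdicts:
                    report.verdicts[p["species"]] = "Unresolved"
            report.warnings.append(f"nucleotide phase failed: {exc}")

    leaf_states = [event_synthesis.LeafState(sp, v)
                   for sp, v in sorted(report.leaf_states.items())]
    if leaf_states:
        states = event_synthesis.sankoff_states(leaf_states, st,
                                                scope_root=config.ancestor)
        mutation_reports = {
            sp: e["mutation_report"] for sp, e in report.evidence.items()
            if isinstance(e, dict) and "mutation_report" in e}
        birth, placements = event_synthesis.place_events(states, st,
                                                         mutation_reports)
        report.birth_node = birth
        report.events = placements
    for e in report.evidence.values():
        e.pop("mutation_report", None)
    return report


def run_batch(jobs: Sequence[tuple]) -> list:
    """Run independent (config, inputs) studies; failures are isolated."""
    out = []
    for config, inputs in jobs:
        try:
            out.append(run_study(config, inputs))
        except PseudotraceError as exc:
            out.append({"error": str(exc),
                        "query": getattr(inputs.query, "id", None)})
    return out


def write_outputs(report: StudyReport, tree: SpeciesTree, outdir) -> None:
    """Write report.json, events.nhx and mutations.tsv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_report_json(report.to_dict(), out / "report.json")

    class _View:
        leaf_states = report.leaf_states
        events = report.events
        birth_node = report.birth_node

    write_annotated_tree(tree, _View, out / "events.nhx")
    with open(out / "mutations.tsv", "w") as fh:
        fh.write("branch\tkind\texon\tposition\tdetail\n")
        for ev in report.events:
            for m in ev.supporting_mutations:
                fh.write(f"{ev.branch[0]}->{ev.branch[1]}\t{m.kind}\t"
                         f"{m.exon_index}\t{m.position}\t{m.detail}\n")


def _nj_guide(aln, taxa: Sequence[str]) -> TreeNode:
    """NJ on TN93 distances over the compacted columns, midpoint-rooted."""
    import numpy as np

    from .gene_tree import build_nj
    from .nucleotide_scan import tn93_distance

    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tn93_distance(aln.rows[taxa[i]],
                                              aln.rows[taxa[j]])
    unrooted = build_nj(D, list(taxa))
    rooted = _midpoint_root(unrooted)
    counter = [0]
    for node in rooted.preorder():
        if not node.is_leaf:
            counter[0] += 1
            node.name = f"A{counter[0]}"
    return rooted


def _midpoint_root(unrooted: TreeNode) -> TreeNode:
    from .gene_tree import _adjacency, _build_rooted, _edges, _leaf_depth

    adj, names = _adjacency(unrooted)
    best = None
    for u, v, w in sorted(_edges(adj)):
        rooted = _build_rooted(adj, names, u, v, w)
        heights = [max(_leaf_depth(c, c.length or 0.0))
                   for c in rooted.children]
        balance = abs(heights[0] - heights[1])
        if best is None or balance < best[0]:
            best = (balance, rooted)
    return best[1]
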