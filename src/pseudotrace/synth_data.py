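"""Seeded generator of complete synthetic study inputs.

A single-copy gene family (exons with canonical GT..AG introns, ATG start,
stop terminator) is evolved down the species tree under a uniform
substitution process (transition:transversion 2:1) and embedded in random
intergenic DNA per species.  Planted events — whole-gene losses and
pseudogenizations built from explicit disabling-mutation recipes — are
applied on chosen branches and recorded, with exact reference-frame
positions, in a machine-readable truth ledger.

Background substitutions are constrained to be non-disabling: they never
create an in-frame stop codon and never touch the start codon, the
terminator or the splice dinucleotides, so the ledger's expected verdicts
are the deterministic consequence of the planted events alone.  Planted
mutation sites are likewise shielded from later background substitutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignment import STOP_CODONS, back_translate, translate
from .errors import DomainError
from .formats_io import (ExonAnnotation, SequenceRecord, write_exon_table,
                         write_fasta)
from .species_tree import SpeciesTree, TreeNode

__all__ = ["PlantedMutation", "PlantedEvent", "SimulationParams",
           "TruthLedger", "SimulatedStudy", "simulate_family",
           "expected_report"]

_NT = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_AA_POOL = "ACDEFGHIKLNPQRSVWY"  # codon-diverse pool for the root protein


@dataclass(frozen=True)
class PlantedMutation:
    """One planted disabling mutation in reference-frame coordinates."""

    kind: str        # nonsense | insertion | deletion | splice_donor |
                     # splice_acceptor | exon_loss
    exon_index: int  # exon (or junction, for splice) index
    position: int    # codon index (nonsense) or nt offset (indels); 0 otherwise
    detail: str = ""


@dataclass(frozen=True)
class PlantedEvent:
    branch: tuple  # (parent_name, child_name) of the species tree
    kind: str      # "loss" | "pseudogenization"
    recipe: tuple = ()  # mutation specs, e.g. (("nonsense",), ("insertion", 4))

    def __post_init__(self):
        if self.kind == "pseudogenization" and not self.recipe:
            raise DomainError("pseudogenization event needs a non-empty recipe")


@dataclass
class SimulationParams:
    tree: SpeciesTree
    # a mid-sized multi-exon gene: losing any single exon leaves most of the
    # protein intact, as for the multi-exon genes such studies target
    exon_lengths: tuple = (90, 90, 90, 90, 90)  # nt, multiples of 3
    intron_lengths: tuple = (80, 80, 80, 80)
    subst_rate: float = 0.02              # substitutions / site / 100 MY
    planted_events: tuple = ()
    unannotated_species: frozenset = frozenset()
    intergenic_length: int = 2000
    seed: int = 0

    def __post_init__(self):
        if any(l % 3 for l in self.exon_lengths):
            raise DomainError("exon lengths must be multiples of 3")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise DomainError("need one intron length per junction")
        if any(l < 24 for l in self.intron_lengths):
            raise DomainError("introns must be >= 24 nt")
        if self.subst_rate < 0:
            raise DomainError("substitution rate must be >= 0")
        branches = {b for b in self._all_branches()}
        for ev in self.planted_events:
            if tuple(ev.branch) not in branches:
                raise DomainError(f"planted branch {ev.branch} not in tree")

    def _all_branches(self):
        for n in self.tree.root.preorder():
            for c in n.children:
                yield (n.name, c.name)


@dataclass
class TruthLedger:
    """Planted events plus the per-species verdicts they imply."""

    events: list       # of (branch, kind, [PlantedMutation, ...])
    verdicts: dict     # species -> Present | Saved | Pseudogene | Lost
    birth_node: str

    def to_json(self) -> dict:
        return {
            "birth_node": self.birth_node,
            "verdicts": dict(sorted(self.verdicts.items())),
            "events": [
                {"branch": list(branch), "kind": kind,
                 "mutations": [vars(m) for m in muts]}
                for branch, kind, muts in self.events],
        }


@dataclass
class SimulatedStudy:
    params: SimulationParams
    genomes: dict       # species -> SequenceRecord (dna)
    proteomes: dict     # species -> list[SequenceRecord]
    annotations: list   # ExonAnnotation for every annotated gene
    ledger: TruthLedger
    gene_loci: dict     # species -> (start, end) of the gene region, or None

    def query_record(self, species: Optional[str] = None) -> SequenceRecord:
        """A Present, annotated protein to use as the study query."""
        if species is None:
            candidates = [sp for sp in self.params.tree.leaf_names
                          if self.ledger.verdicts[sp] == "Present"]
            if not candidates:
                raise DomainError("no Present species to draw a query from")
            species = candidates[0]
        return self.proteomes[species][0]

    def write(self, outdir) -> None:
        out = Path(outdir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        (out / "proteomes").mkdir(parents=True, exist_ok=True)
        for sp, rec in sorted(self.genomes.items()):
            write_fasta([rec], out / "genomes" / f"{sp}.fa")
        for sp, recs in sorted(self.proteomes.items()):
            if recs:
                write_fasta(recs, out / "proteomes" / f"{sp}.fa")
        write_exon_table(self.annotations, out / "exons.tsv")
        (out / "species_tree.nwk").write_text(self.params.tree.to_newick() + "\n")
        (out / "truth.json").write_text(
            json.dumps(self.ledger.to_json(), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------

@dataclass
class _GeneState:
    exons: list          # list[str], reference exon grid (lost exons are "")
    introns: list        # list[str]
    left: str = ""       # flanking intergenic DNA, inherited down the tree
    right: str = ""
    lost: bool = False
    pseudo: bool = False
    shield: set = field(default_factory=set)  # (exon_idx, nt_offset) no-touch

    def clone(self) -> "_GeneState":
        return _GeneState(list(self.exons), list(self.introns), self.left,
                          self.right, self.lost, self.pseudo,
                          set(self.shield))

    def sequence(self) -> str:
        parts = []
        for i, ex in enumerate(self.exons):
            parts.append(ex)
            if i < len(self.introns):
                parts.append(self.introns[i])
        return "".join(parts)

    def cds(self) -> str:
        return "".join(self.exons)


def _random_dna(rng, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=n))


def _make_root_gene(params: SimulationParams, rng) -> _GeneState:
    total_cds = sum(params.exon_lengths)
    n_aa = total_cds // 3 - 2  # minus start and stop codons
    body = "".join(_AA_POOL[i] for i in rng.integers(0, len(_AA_POOL), n_aa))
    cds = "ATG" + back_translate(body) + "TAA"
    assert len(cds) == total_cds
    exons = []
    pos = 0
    for l in params.exon_lengths:
        exons.append(cds[pos:pos + l])
        pos += l
    introns = []
    for l in params.intron_lengths:
        introns.append("GT" + _random_dna(rng, l - 4) + "AG")
    left = _random_dna(rng, params.intergenic_length)
    right = _random_dna(rng, params.intergenic_length)
    return _GeneState(exons, introns, left, right)


def _apply_substitutions(state: _GeneState, n_sub: int, rng) -> None:
    """Seeded background substitutions, constrained to be non-disabling.

    Intergenic flanks evolve freely; coding and splice positions are
    protected from disabling changes (see module docstring).
    """
    if n_sub <= 0:
        return
    exon_len = [len(e) for e in state.exons] if not state.lost else []
    intron_len = [len(i) for i in state.introns] if not state.lost else []
    cum = []  # (kind, idx, length) flattened regions
    cum.append(("l", 0, len(state.left)))
    for i, l in enumerate(exon_len):
        cum.append(("e", i, l))
        if i < len(intron_len):
            cum.append(("i", i, intron_len[i]))
    cum.append(("r", 0, len(state.right)))
    total = sum(l for _, _, l in cum)
    if total == 0:
        return
    applied = 0
    attempts = 0
    while applied < n_sub and attempts < 50 * n_sub + 200:
        attempts += 1
        p = int(rng.integers(0, total))
        kind = idx = off = None
        for k, i, l in cum:
            if p < l:
                kind, idx, off = k, i, p
                break
            p -= l
        if kind in ("l", "r"):
            seq = state.left if kind == "l" else state.right
            new = _draw_base(seq[off], rng)
            edited = seq[:off] + new + seq[off + 1:]
            if kind == "l":
                state.left = edited
            else:
                state.right = edited
            applied += 1
            continue
        if kind == "i":
            if off < 2 or off >= intron_len[idx] - 2:
                continue  # splice dinucleotides are background-immutable
            seq = state.introns[idx]
            new = _draw_base(seq[off], rng)
            state.introns[idx] = seq[:off] + new + seq[off + 1:]
            applied += 1
            continue
        # exon position
        if (idx, off) in state.shield:
            continue
        cds_off = sum(exon_len[:idx]) + off
        cds = state.cds()
        if cds_off < 3 or cds_off >= len(cds) - 3:
            continue  # start and terminator codons stay put
        new = _draw_base(state.exons[idx][off], rng)
        codon_start = cds_off - cds_off % 3
        codon = list(cds[codon_start:codon_start + 3])
        codon[cds_off % 3] = new
        if "".join(codon) in STOP_CODONS:
            continue  # background never creates a nonsense codon
        seq = state.exons[idx]
        state.exons[idx] = seq[:off] + new + seq[off + 1:]
        applied += 1


def _draw_base(old: str, rng) -> str:
    if rng.random() < 2.0 / 3.0:
        return _TRANSITION.get(old, "A")
    tv = _TRANSVERSIONS.get(old, "AC")
    return tv[int(rng.integers(0, 2))]


def _unambiguous_insert(seq: str, off: int, length: int) -> str:
    """Inserted run whose first/last bases differ from the flanking bases,
    so single-base shifts of the insertion cannot yield the same string."""
    ins = list(("GTCA" * (length // 4 + 1))[:length])
    left = seq[off - 1] if off > 0 else ""
    right = seq[off] if off < len(seq) else ""
    if length == 1:
        ins[0] = next(c for c in "ACGT" if c not in (left, right))
    else:
        if ins[0] == right:
            ins[0] = next(c for c in "ACGT" if c != right)
        if ins[-1] == left:
            ins[-1] = next(c for c in "ACGT" if c != left)
    return "".join(ins)


def _apply_recipe(state: _GeneState, recipe, rng) -> list[PlantedMutation]:
    """Apply a pseudogenization recipe; returns reference-frame records.

    Indels are applied after substit-type edits and from the 3' end first,
    so every recorded position stays valid in reference coordinates.
    Mutations avoid the 10 nt nearest every exon boundary unless they target
    a splice site.
    """
    muts: list[PlantedMutation] = []
    n_exons = len(state.exons)
    inner = list(range(1, n_exons - 1)) or [0]
    subs = [r for r in recipe if r[0] == "nonsense"]
    splices = [r for r in recipe if r[0] in ("splice_donor", "splice_acceptor")]
    indels = [r for r in recipe if r[0] in ("insertion", "deletion")]
    exon_losses = [r for r in recipe if r[0] == "exon_loss"]
    other = [r for r in recipe
             if r[0] not in ("nonsense", "splice_donor", "splice_acceptor",
                             "insertion", "deletion", "exon_loss")]
    if other:
        raise DomainError(f"unknown recipe entries: {other}")

    used_codons: set[tuple[int, int]] = set()
    for _ in subs:
        for _try in range(100):
            ei = inner[int(rng.integers(0, len(inner)))]
            ncod = len(state.exons[ei]) // 3
            lo, hi = 4, ncod - 4  # keep 10+ nt off the boundaries
            if hi <= lo:
                continue
            ci = int(rng.integers(lo, hi))
            if (ei, ci) in used_codons:
                continue
            used_codons.add((ei, ci))
            seq = state.exons[ei]
            state.exons[ei] = seq[:3 * ci] + "TAA" + seq[3 * ci + 3:]
            for k in range(3):
                state.shield.add((ei, 3 * ci + k))
            muts.append(PlantedMutation("nonsense", ei, ci, "TAA"))
            break
        else:
            raise DomainError("could not place nonsense mutation")

    used_junctions: set[int] = set()
    for spec in splices:
        side = spec[0]
        for _try in range(100):
            j = int(rng.integers(0, len(state.introns)))
            if j in used_junctions:
                continue
            used_junctions.add(j)
            intr = state.introns[j]
            if side == "splice_donor":
                new_di = "G" + "AC"[int(rng.integers(0, 2))]
                state.introns[j] = new_di + intr[2:]
            else:
                new_di = "AT" if rng.random() < 0.5 else "GG"
                state.introns[j] = intr[:-2] + new_di
            muts.append(PlantedMutation(side, j, 0, new_di))
            break
        else:
            raise DomainError("could not place splice mutation")

    indel_sites = []
    for spec in indels:
        kind, length = spec[0], int(spec[1])
        if length < 1:
            raise DomainError("indel length must be >= 1")
        for _try in range(200):
            ei = inner[int(rng.integers(0, len(inner)))]
            seq = state.exons[ei]
            elen = len(seq)
            lo, hi = 12, elen - 12 - (length if kind == "deletion" else 0)
            if hi <= lo:
                continue
            off = int(rng.integers(lo, hi))
            if any(e == ei and abs(o - off) < length + 6
                   for _, e, o, _l, _p in indel_sites):
                continue
            if any(e == ei and abs(3 * c - off) < length + 9
                   for e, c in used_codons):
                continue  # keep indels clear of planted nonsense codons
            # an indel that could sit at a nearby offset with an identical
            # result shifts under alignment; keep truth positions unambiguous
            if kind == "deletion":
                result = seq[:off] + seq[off + length:]
                payload = None
            else:
                payload = _unambiguous_insert(seq, off, length)
                result = seq[:off] + payload + seq[off:]
            ambiguous = False
            for s in range(-6, 7):
                o2 = off + s
                if s == 0 or o2 < 0:
                    continue
                if kind == "deletion":
                    if o2 + length <= elen and \
                            seq[:o2] + seq[o2 + length:] == result:
                        ambiguous = True
                        break
                else:
                    if o2 + length <= len(result) and \
                            seq[:o2] + result[o2:o2 + length] + seq[o2:] \
                            == result:
                        ambiguous = True
                        break
            if ambiguous:
                continue
            indel_sites.append((kind, ei, off, length, payload))
            break
        else:
            raise DomainError("could not place indel")
    # 3'-first application keeps reference offsets stable
    for kind, ei, off, length, payload in sorted(
            indel_sites, key=lambda t: (-t[1], -t[2])):
        seq = state.exons[ei]
        if kind == "deletion":
            state.exons[ei] = seq[:off] + seq[off + length:]
        else:
            state.exons[ei] = seq[:off] + payload + seq[off:]
        muts.append(PlantedMutation(kind, ei, off, str(length)))

    for _ in exon_losses:
        candidates = [i for i in inner
                      if state.exons[i] and i not in {m.exon_index for m in muts}]
        if not candidates:
            raise DomainError("no exon available for exon_loss")
        ei = candidates[int(rng.integers(0, len(candidates)))]
        state.exons[ei] = ""
        muts.append(PlantedMutation("exon_loss", ei, 0))

    state.pseudo = True
    state.shield |= {(m.exon_index, p) for m in muts if m.kind == "nonsense"
                     for p in range(3 * m.position, 3 * m.position + 3)}
    muts.sort(key=lambda m: (m.exon_index, m.position, m.kind))
    return muts


def simulate_family(params: SimulationParams) -> SimulatedStudy:
    """Evolve the family down the tree and assemble genomes/proteomes."""
    rng = np.random.default_rng(int(params.seed) % (2 ** 31))
    tree = params.tree
    root_gene = _make_root_gene(params, rng)

    events_by_branch = {}
    for ev in params.planted_events:
        events_by_branch.setdefault(tuple(ev.branch), []).append(ev)

    ledger_events: list = []
    states: dict[str, _GeneState] = {tree.root.name: root_gene}

    for node in tree.root.preorder():
        if node is tree.root:
            continue
        branch = (node.parent.name, node.name)
        state = states[node.parent.name].clone()
        genome_len = (len(state.left) + len(state.right)
                      + (0 if state.lost else len(state.sequence())))
        lam = (params.subst_rate / 100.0) * float(node.length) * genome_len
        n_sub = int(rng.poisson(lam)) if lam > 0 else 0
        _apply_substitutions(state, n_sub, rng)
        if not state.lost:
            for ev in events_by_branch.get(branch, []):
                if ev.kind == "loss":
                    state.lost = True
                    ledger_events.append((branch, "loss", []))
                elif ev.kind == "pseudogenization":
                    muts = _apply_recipe(state, ev.recipe, rng)
                    ledger_events.append((branch, "pseudogenization", muts))
                else:
                    raise DomainError(f"unknown event kind {ev.kind!r}")
        states[node.name] = state

    genomes: dict[str, SequenceRecord] = {}
    proteomes: dict[str, list] = {}
    annotations: list[ExonAnnotation] = []
    gene_loci: dict[str, Optional[tuple]] = {}
    verdicts: dict[str, str] = {}

    for sp in tree.leaf_names:
        state = states[sp]
        left, right = state.left, state.right
        if state.lost:
            genome_seq = left + right
            gene_loci[sp] = None
            verdicts[sp] = "Lost"
        else:
            gene = state.sequence()
            genome_seq = left + gene + right
            gene_loci[sp] = (len(left), len(left) + len(gene))
            if state.pseudo:
                verdicts[sp] = "Pseudogene"
            elif sp in params.unannotated_species:
                verdicts[sp] = "Saved"
            else:
                verdicts[sp] = "Present"
        genomes[sp] = SequenceRecord(id=f"{sp}_chr1", species=sp,
                                     seq=genome_seq, kind="dna")
        proteomes[sp] = []
        if verdicts[sp] == "Present":
            protein = translate(state.cds())
            if protein.endswith("*"):
                protein = protein[:-1]
            proteomes[sp].append(SequenceRecord(
                id=f"{sp}|g1", species=sp, seq=protein, kind="protein"))
            exon_ivals = []
            pos = gene_loci[sp][0]
            for i, ex in enumerate(state.exons):
                exon_ivals.append((pos, pos + len(ex)))
                pos += len(ex)
                if i < len(state.introns):
                    pos += len(state.introns[i])
            annotations.append(ExonAnnotation(
                gene_id=f"{sp}|g1", species=sp, chrom=f"{sp}_chr1",
                strand="+", exons=tuple(exon_ivals)))

    ledger = TruthLedger(events=ledger_events, verdicts=verdicts,
                         birth_node=tree.root.name)
    return SimulatedStudy(params=params, genomes=genomes, proteomes=proteomes,
                          annotations=annotations, ledger=ledger,
                          gene_loci=gene_loci)


def expected_report(ledger: TruthLedger) -> dict:
    """The study report the pipeline should reproduce, from the ledger."""
    return {
        "verdicts": dict(sorted(ledger.verdicts.items())),
        "events": sorted(
            (tuple(branch), "gene_loss" if kind == "loss" else "pseudogenization")
            for branch, kind, _ in ledger.events),
        "birth_node": ledger.birth_node,
    }
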