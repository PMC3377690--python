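"""Nucleotide-level forensics: ancestors, exon projection, mutation scan.

The loci selected for reconstruction are aligned together, the alignment is
compacted to the reference exon regions (plus a short retained intron flank
at every junction so splice dinucleotides stay visible), ancestral rows are
reconstructed for every internal node of the guide tree by Sankoff parsimony
over the 5-state alphabet {A,C,G,T,-}, and each branch is scanned
descendant-vs-ancestor for disabling mutations: start/stop codon loss,
nonsense codons, insertions and deletions (frameshift when length is not a
multiple of three), splice-site changes and exon losses.  All positions are
read in the reading frame projected from the annotated reference gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import STOP_CODONS, global_align, mafft_msa
from .errors import DomainError, InsufficientDataError, PseudotraceError
from .formats_io import SequenceRecord
from .species_tree import TreeNode

__all__ = [
    "Mutation", "MutationReport", "CompactedAlignment",
    "KnownOrtholog", "CandidateLocus",
    "select_reconstruction_set", "build_guided_alignment",
    "reconstruct_ancestors", "scan_pair", "scan_lineage", "classify_sequence",
    "tn93_distance", "ProjectionFailure",
]

DISABLING_KINDS = {"nonsense", "frameshift", "splice_donor", "splice_acceptor",
                   "start_loss", "stop_loss", "exon_loss"}

STATES = "ACGT-"
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
INF = 10 ** 9


class ProjectionFailure(PseudotraceError):
    """Reference exons could not be projected through the alignment."""


@dataclass
class Mutation:
    """One typed disabling (or neutral indel) mutation.

    ``position`` is 0-based within the exon, in reference-projection
    coordinates: a codon index for nonsense/start/stop, a nucleotide offset
    for indels, and 0 for splice/exon-level events.
    """

    kind: str
    exon_index: int
    position: int
    detail: str = ""
    branch: Optional[tuple] = None  # (parent_name, child_name) on the guide tree


@dataclass
class MutationReport:
    """Mutations attributed to the branches on one target's root-to-leaf path."""

    target: str
    mutations: list = field(default_factory=list)
    low_confidence_exons: list = field(default_factory=list)


@dataclass(frozen=True)
class KnownOrtholog:
    species: str
    protein: SequenceRecord
    locus: SequenceRecord  # gene region DNA in transcript orientation
    exons_local: tuple     # exon (start, end) intervals in locus coordinates


@dataclass(frozen=True)
class CandidateLocus:
    species: str
    locus: SequenceRecord
    similarity_pct: float  # best protein-level identity to the scan reference


# ---------------------------------------------------------------------------
# Reconstruction-set selection (test 3)

def select_reconstruction_set(knowns: Sequence[KnownOrtholog],
                              candidates: Sequence[CandidateLocus],
                              reference_protein: SequenceRecord,
                              max_divergence_pct: float = 60.0,
                              ) -> tuple[list[KnownOrtholog], list[CandidateLocus]]:
    """Keep one sequence per species; drop too-divergent knowns.

    A known ortholog is kept when its protein identity to the scan reference
    is at least (100 - max_divergence); among several sequences of one
    species the most reference-similar survives.  Candidates under scan are
    always retained.  Fewer than 3 surviving sequences raise
    InsufficientDataError (the caller falls back to the protein-level
    verdict).
    """
    if not candidates:
        raise DomainError("no candidate loci under scan")
    if len(knowns) < 2:
        raise InsufficientDataError("need at least 2 known orthologs")
    best_by_species: dict[str, tuple[float, KnownOrtholog]] = {}
    for kn in knowns:
        ident = _identity_pct(kn.protein.seq, reference_protein.seq)
        if ident < 100.0 - max_divergence_pct:
            continue
        cur = best_by_species.get(kn.species)
        if cur is None or ident > cur[0]:
            best_by_species[kn.species] = (ident, kn)
    survivors = [kn for _, kn in sorted(best_by_species.values(),
                                        key=lambda t: t[1].species)]
    cand_species = {c.species for c in candidates}
    survivors = [kn for kn in survivors if kn.species not in cand_species]
    best_cand: dict[str, CandidateLocus] = {}
    for c in candidates:
        cur = best_cand.get(c.species)
        if cur is None or c.similarity_pct > cur.similarity_pct:
            best_cand[c.species] = c
    cands = [best_cand[sp] for sp in sorted(best_cand)]
    if len(survivors) + len(cands) < 3:
        raise InsufficientDataError(
            f"only {len(survivors) + len(cands)} sequences survive test 3")
    return survivors, cands


def _identity_pct(a: str, b: str) -> float:
    _, ga, gb = global_align(a, b)
    same = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return 100.0 * same / len(ga)


# ---------------------------------------------------------------------------
# Guided alignment + compaction

@dataclass
class CompactedAlignment:
    """Equal-length gapped rows compacted to reference exon regions."""

    rows: dict                    # taxon -> gapped sequence (str)
    reference: str                # taxon name of the annotated reference row
    exon_columns: list            # per exon: np.ndarray of reference non-gap columns
    exon_intervals: list          # per exon: (first_col, last_col + 1) span
    donor_columns: list           # per junction: columns of first 2 intron nt
    acceptor_columns: list        # per junction: columns of last 2 intron nt
    column_map: dict              # taxon -> np.ndarray: column -> locus pos (-1 at gaps)
    low_confidence_exons: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list:
        return sorted(self.rows)


def build_guided_alignment(seqs: Sequence[SequenceRecord], reference_name: str,
                           reference_exons_local: Sequence[tuple],
                           flank: int = 20) -> CompactedAlignment:
    """Align loci, keep reference exon regions ± ``flank`` nt, project exons.

    ``reference_exons_local`` are (start, end) intervals in the reference
    locus' own coordinates, 5'->3'.  The retained flank keeps the splice
    dinucleotides of every junction in view for the scan.
    """
    names = [s.id for s in seqs]
    if reference_name not in names:
        raise DomainError(f"reference {reference_name!r} not among sequences")
    if len(seqs) < 3:
        raise InsufficientDataError("guided alignment needs >= 3 sequences")
    aligned = dict(mafft_msa([(s.id, s.seq) for s in seqs], kind="dna"))
    ref_row = aligned[reference_name]
    ncol = len(ref_row)

    # reference locus position -> alignment column
    ref_cols = np.flatnonzero(np.frombuffer(ref_row.encode(), dtype=np.uint8)
                              != ord("-"))
    ref_len = len(ref_cols)
    for s, e in reference_exons_local:
        if not (0 <= s < e <= ref_len):
            raise DomainError("reference exon outside locus")

    other = [aligned[n] for n in names if n != reference_name]
    arr_other = np.array([list(r) for r in other]) if other else None
    exonic_cols = np.concatenate([ref_cols[s:e] for s, e in reference_exons_local])
    if arr_other is not None:
        covered = (arr_other[:, exonic_cols] != "-").any(axis=0)
        if covered.mean() < 0.5:
            raise ProjectionFailure(
                "reference exonic positions align to gaps in every other row "
                f"at {100 * (1 - covered.mean()):.0f}% of sites")

    keep_mask = np.zeros(ncol, dtype=bool)
    for s, e in reference_exons_local:
        lo = max(0, s - flank)
        hi = min(ref_len, e + flank)
        keep_mask[ref_cols[lo]:ref_cols[hi - 1] + 1] = True
    keep = np.flatnonzero(keep_mask)
    old_to_new = -np.ones(ncol, dtype=np.int64)
    old_to_new[keep] = np.arange(len(keep))

    rows = {}
    column_map = {}
    pos_of = {}
    for name in names:
        row = aligned[name]
        arr = np.array(list(row))
        compacted = arr[keep]
        rows[name] = "".join(compacted)
        locus_pos = np.where(arr != "-",
                             np.cumsum(arr != "-") - 1, -1)
        column_map[name] = locus_pos[keep]

    new_ref_cols = old_to_new[ref_cols]  # reference locus pos -> compacted col

    exon_columns = []
    exon_intervals = []
    for s, e in reference_exons_local:
        cols = new_ref_cols[s:e]
        exon_columns.append(cols)
        exon_intervals.append((int(cols[0]), int(cols[-1]) + 1))

    donor_cols, acceptor_cols = [], []
    for k in range(len(reference_exons_local) - 1):
        e_end = reference_exons_local[k][1]
        n_start = reference_exons_local[k + 1][0]
        if n_start - e_end >= 4:
            donor_cols.append(new_ref_cols[e_end:e_end + 2])
            acceptor_cols.append(new_ref_cols[n_start - 2:n_start])
        else:  # abutting exons (no intron): nothing to test
            donor_cols.append(np.array([], dtype=np.int64))
            acceptor_cols.append(np.array([], dtype=np.int64))

    aln = CompactedAlignment(rows=rows, reference=reference_name,
                             exon_columns=exon_columns,
                             exon_intervals=exon_intervals,
                             donor_columns=donor_cols,
                             acceptor_columns=acceptor_cols,
                             column_map=column_map)
    aln.low_confidence_exons = _flag_low_confidence(aln)
    return aln


def _flag_low_confidence(aln: CompactedAlignment) -> list:
    """Exons whose boundary columns align to gap in at least half the rows.

    Misprojected exon boundaries shift the scanning frame silently; such
    exons are flagged rather than trusted.
    """
    flags = []
    others = [r for n, r in aln.rows.items() if n != aln.reference]
    if not others:
        return flags
    arr = np.array([list(r) for r in others])
    for k, cols in enumerate(aln.exon_columns):
        edge = np.concatenate([cols[:3], cols[-3:]])
        gappy_rows = (arr[:, edge] == "-").sum(axis=1) > 2
        if gappy_rows.sum() * 2 >= len(others):
            flags.append(k)
    return flags


# ---------------------------------------------------------------------------
# Ancestral reconstruction (Sankoff parsimony over {A,C,G,T,-})

def reconstruct_ancestors(aln: CompactedAlignment, guide: TreeNode,
                          ) -> dict[str, str]:
    """Sankoff parsimony ancestral rows for every internal guide-tree node.

    Unit cost for every state change (substitutions and gap transitions
    alike); ties are resolved in a preorder pass preferring the parent's
    state, then the fixed order A, C, G, T, '-'.  Returns internal node name
    -> reconstructed row.
    """
    leaves = guide.leaf_names()
    if len(leaves) < 3:
        raise DomainError("reconstruction needs >= 3 rows")
    missing = [l for l in leaves if l not in aln.rows]
    if missing:
        raise DomainError(f"guide leaves without rows: {missing}")
    ncol = aln.n_columns
    nstate = len(STATES)
    cost_matrix = np.ones((nstate, nstate)) - np.eye(nstate)

    costs: dict[int, np.ndarray] = {}
    for node in guide.postorder():
        if node.is_leaf:
            c = np.full((ncol, nstate), INF, dtype=float)
            row = aln.rows[node.name]
            for j, ch in enumerate(row):
                if ch in _STATE_INDEX:
                    c[j, _STATE_INDEX[ch]] = 0
                else:  # N or other ambiguity: any nucleotide free, gap costs 1
                    c[j, :4] = 0
                    c[j, 4] = 1
            costs[id(node)] = c
        else:
            total = np.zeros((ncol, nstate))
            for child in node.children:
                cc = costs[id(child)]
                m = cc.min(axis=1, keepdims=True)
                total += np.minimum(cc, m + 1)
            costs[id(node)] = total

    # preorder resolution with deterministic tie-breaks
    assigned: dict[int, np.ndarray] = {}
    order_bias = np.arange(1, nstate + 1, dtype=float)  # A<C<G<T<'-'
    for node in guide.preorder():
        c = costs[id(node)]
        if node.parent is None:
            score = c * 10 + order_bias
        else:
            parent_states = assigned[id(node.parent)]
            trans = cost_matrix[parent_states]  # (ncol, nstate)
            bias = np.tile(order_bias, (ncol, 1))
            bias[np.arange(ncol), parent_states] = 0  # prefer parent state
            score = (c + trans) * 10 + bias
        assigned[id(node)] = np.argmin(score, axis=1)

    out = {}
    for node in guide.preorder():
        if not node.is_leaf:
            out[node.name] = "".join(STATES[s] for s in assigned[id(node)])
    return out


# ---------------------------------------------------------------------------
# Guide-tree distance (TN93 closed form) for the unforced topology option

def tn93_distance(a: str, b: str) -> float:
    """Tamura–Nei 1993 distance between two gapped rows (shared sites only).

    Falls back to a capped value when the closed form is undefined
    (saturation).
    """
    pairs = [(x, y) for x, y in zip(a, b)
             if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    if n == 0:
        return 5.0
    freq = {s: 0.0 for s in "ACGT"}
    for x, y in pairs:
        freq[x] += 0.5 / n
        freq[y] += 0.5 / n
    gR = freq["A"] + freq["G"]
    gY = freq["C"] + freq["T"]
    p1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n  # purine ts
    p2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n  # pyrimidine ts
    q = sum(1 for x, y in pairs
            if (x in "AG") != (y in "AG")) / n                 # transversions
    try:
        k1 = 2 * freq["A"] * freq["G"] / gR if gR > 0 else 0
        k2 = 2 * freq["C"] * freq["T"] / gY if gY > 0 else 0
        k3 = 2 * (gR * gY - freq["A"] * freq["G"] * gY / gR
                  - freq["C"] * freq["T"] * gR / gY)
        w1 = 1 - p1 / k1 - q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - p2 / k2 - q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - q / k3 if k3 > 0 else 1.0
        d = 0.0
        if k1 > 0:
            d += -k1 * math.log(w1)
        if k2 > 0:
            d += -k2 * math.log(w2)
        if k3 > 0:
            d += -k3 * math.log(w3)
        return d
    except ValueError:  # log of non-positive: saturated
        return 5.0


# ---------------------------------------------------------------------------
# The branch scan

def _codon(row: str, cols) -> Optional[str]:
    chars = [row[c] for c in cols]
    if "-" in chars:
        return None
    return "".join(chars)


def scan_pair(descendant_row: str, ancestor_row: str,
              aln: CompactedAlignment,
              branch: Optional[tuple] = None) -> list[Mutation]:
    """Compare one row against its ancestor within the projected exons."""
    if len(descendant_row) != len(ancestor_row):
        raise DomainError("rows differ in length")
    muts: list[Mutation] = []
    n_exons = len(aln.exon_columns)
    frame_offset = 0  # nt carried over across exons for codon phase

    for k, cols in enumerate(aln.exon_columns):
        d_gap = np.fromiter((descendant_row[c] == "-" for c in cols),
                            dtype=bool, count=len(cols))
        a_gap = np.fromiter((ancestor_row[c] == "-" for c in cols),
                            dtype=bool, count=len(cols))
        if d_gap.mean() >= 0.9 and a_gap.mean() < 0.5:
            muts.append(Mutation("exon_loss", k, 0, branch=branch))
            frame_offset = (frame_offset + len(cols)) % 3
            continue

        # indels: gap runs over the exon's full column span, present in one
        # row only (columns where the reference itself has a gap count too)
        lo, hi = aln.exon_intervals[k]
        _indel_runs(descendant_row, ancestor_row, lo, hi, k, cols, muts, branch)

        # codon scan in the projected frame (phase carried across junctions)
        start = (3 - frame_offset) % 3
        for c0 in range(start, len(cols) - 2, 3):
            triplet = cols[c0:c0 + 3]
            d_codon = _codon(descendant_row, triplet)
            a_codon = _codon(ancestor_row, triplet)
            if d_codon is None or a_codon is None:
                continue
            codon_index = c0 // 3
            is_first = (k == 0 and c0 == 0)
            is_last = (k == n_exons - 1 and c0 + 3 >= len(cols))
            if is_first:
                if a_codon == "ATG" and d_codon != "ATG":
                    muts.append(Mutation("start_loss", k, 0, d_codon, branch))
                continue
            if is_last:
                if a_codon in STOP_CODONS and d_codon not in STOP_CODONS:
                    muts.append(Mutation("stop_loss", k, codon_index,
                                         d_codon, branch))
                continue
            if d_codon in STOP_CODONS and a_codon not in STOP_CODONS:
                muts.append(Mutation("nonsense", k, codon_index, d_codon,
                                     branch))
        frame_offset = (frame_offset + len(cols)) % 3

    for k in range(n_exons - 1):
        for name, jcols in (("splice_donor", aln.donor_columns[k]),
                            ("splice_acceptor", aln.acceptor_columns[k])):
            if len(jcols) < 2:
                continue
            d_di = _codon(descendant_row, jcols)
            a_di = _codon(ancestor_row, jcols)
            canonical = "GT" if name == "splice_donor" else "AG"
            if a_di == canonical and d_di is not None and d_di != canonical:
                muts.append(Mutation(name, k, 0, d_di, branch))
    return muts


def _indel_runs(d_row: str, a_row: str, lo: int, hi: int, exon: int,
                ref_cols, muts: list, branch) -> None:
    ref_col_set = {int(c): i for i, c in enumerate(ref_cols)}

    def nt_offset(col: int) -> int:
        # nt offset within the exon of the nearest reference position
        while col < hi:
            if col in ref_col_set:
                return ref_col_set[col]
            col += 1
        return len(ref_col_set)

    c = lo
    while c < hi:
        d_g, a_g = d_row[c] == "-", a_row[c] == "-"
        if d_g and not a_g:
            start = c
            while c < hi and d_row[c] == "-" and a_row[c] != "-":
                c += 1
            length = c - start
            pos = nt_offset(start)
            muts.append(Mutation("deletion", exon, pos, str(length), branch))
            if length % 3 != 0:
                muts.append(Mutation("frameshift", exon, pos, str(length),
                                     branch))
        elif a_g and not d_g:
            start = c
            while c < hi and a_row[c] == "-" and d_row[c] != "-":
                c += 1
            length = c - start
            pos = nt_offset(start)
            muts.append(Mutation("insertion", exon, pos, str(length), branch))
            if length % 3 != 0:
                muts.append(Mutation("frameshift", exon, pos, str(length),
                                     branch))
        else:
            c += 1


def scan_lineage(aln: CompactedAlignment, ancestors: dict[str, str],
                 guide: TreeNode, targets: Sequence[str],
                 ) -> dict[str, MutationReport]:
    """Scan every branch on the paths from the guide root to each target.

    A mutation found on an ancestor-vs-ancestor branch is reported once, on
    that internal branch, and appears in the report of every target below
    it.
    """
    rows = dict(aln.rows)
    rows.update(ancestors)
    node_of = {n.name: n for n in guide.preorder()}
    for t in targets:
        if t not in node_of:
            raise DomainError(f"target {t!r} not in guide tree")

    branch_cache: dict[tuple, list[Mutation]] = {}

    def path_branches(target: str):
        out = []
        n = node_of[target]
        while n.parent is not None:
            out.append((n.parent.name, n.name))
            n = n.parent
        return list(reversed(out))

    reports = {}
    for t in targets:
        rep = MutationReport(target=t,
                             low_confidence_exons=list(aln.low_confidence_exons))
        for branch in path_branches(t):
            if branch not in branch_cache:
                parent, child = branch
                branch_cache[branch] = scan_pair(rows[child], rows[parent],
                                                 aln, branch=branch)
            rep.mutations.extend(branch_cache[branch])
        reports[t] = rep
    return reports


def classify_sequence(report: MutationReport) -> str:
    """'pseudogene' iff any disabling mutation lies on the target's path;
    in-frame indels alone do not condemn."""
    for m in report.mutations:
        if m.kind in DISABLING_KINDS:
            return "pseudogene"
    return "intact"
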