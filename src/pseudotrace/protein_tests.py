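"""Protein-level decision tests.

Two decisions are made at protein level.  Test 1 (the signal gate) chooses
the depth of the analysis: a recovered sequence whose identity and length
ratio versus the reference both exceed the configured thresholds is clean
enough for the nucleotide-level scan, otherwise the verdict must come from
protein conservation alone.  Test 2 (the conservation test) asks whether the
conservation of a recovered protein is consistent with the divergence times
of the species involved: identity is assumed inversely proportional to
divergence time, so with a calibration pair of known orthologs at divergence
D2 and identity Value2, a candidate pair at divergence D1 must exceed the
relative threshold D2·Value2/D1 to be called a putative gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .alignment import global_align
from .errors import DomainError, InsufficientDataError
from .formats_io import SequenceRecord
from .species_tree import SpeciesTree

__all__ = ["SimilarityResult", "ConservationTestInput", "global_identity",
           "signal_gate", "conservation_test", "select_known_pair"]


@dataclass(frozen=True)
class SimilarityResult:
    identity_pct: float      # identical residues / alignment columns x 100
    length_ratio_pct: float  # 100 x candidate length / reference length
    score: float
    aligned_candidate: str
    aligned_reference: str


@dataclass
class ConservationTestInput:
    candidate_species: str
    mode: str                # "distinct_lca" | "same_lca"
    d1: float                # MY divergence of the candidate pair
    d2: float                # MY divergence of the calibration (known) pair
    value1: float            # identity % of the candidate pair
    value2: float            # identity % of the known pair
    nearer_known: str = ""
    known_pair: tuple = ()


def global_identity(candidate: str, reference: str) -> SimilarityResult:
    """Needleman–Wunsch identity over the full alignment length.

    Gap columns count in the denominator, so truncated fragments score low
    on identity as well as on length ratio.
    """
    if not candidate or not reference:
        raise DomainError("global_identity requires non-empty sequences")
    score, gc, gr = global_align(candidate, reference)
    identical = sum(1 for a, b in zip(gc, gr) if a == b and a != "-")
    return SimilarityResult(
        identity_pct=100.0 * identical / len(gc),
        length_ratio_pct=100.0 * len(candidate) / len(reference),
        score=score, aligned_candidate=gc, aligned_reference=gr)


def signal_gate(hit_protein: str, predicted: Optional[str], reference: str,
                similarity_pct: float = 50.0,
                length_pct: float = 60.0) -> str:
    """Test 1: 'nucleotide_level' when either tested sequence exceeds both
    thresholds versus the reference, 'protein_level' otherwise."""
    if not reference or not hit_protein:
        raise DomainError("signal_gate requires reference and hit sequences")
    for seq in (hit_protein, predicted):
        if not seq:
            continue
        r = global_identity(seq, reference)
        if r.identity_pct >= similarity_pct and r.length_ratio_pct >= length_pct:
            return "nucleotide_level"
    return "protein_level"


def conservation_test(inp: ConservationTestInput) -> str:
    """Test 2: 'putative_gene' or 'putative_pseudogene'.

    distinct_lca: the candidate-vs-nearer-known identity must beat the
    identity between the two more-divergent knowns.  same_lca: the candidate
    identity must beat the relative threshold D2·Value2/D1.
    """
    if inp.mode == "distinct_lca":
        return "putative_gene" if inp.value1 > inp.value2 else "putative_pseudogene"
    if inp.mode == "same_lca":
        if inp.d1 <= 0 or inp.d2 <= 0:
            raise DomainError("divergence times must be positive")
        threshold = inp.d2 * inp.value2 / inp.d1
        return "putative_gene" if inp.value1 > threshold else "putative_pseudogene"
    raise DomainError(f"unknown mode {inp.mode!r}")


def select_known_pair(candidate: SequenceRecord,
                      knowns: Sequence[SequenceRecord],
                      tree: SpeciesTree) -> ConservationTestInput:
    """Choose the test mode and the proteins entering the conservation test.

    With several known species, at most one protein per species is kept (the
    one most similar to the candidate).  distinct_lca mode applies when two
    knowns have different LCAs with the candidate species; the nearest known
    carries Value1/D1 and the most mutually divergent known pair carries
    Value2/D2.  With a single shared LCA, the most divergent known pair
    calibrates the expected identity decay instead, and Value1 is the
    candidate's best identity to a member of that pair.
    """
    sp = candidate.species
    by_species: dict[str, tuple[float, SequenceRecord]] = {}
    for kn in knowns:
        if kn.species == sp:
            continue
        ident = global_identity(candidate.seq, kn.seq).identity_pct
        cur = by_species.get(kn.species)
        if cur is None or ident > cur[0]:
            by_species[kn.species] = (ident, kn)
    if len(by_species) < 2:
        raise InsufficientDataError(
            "conservation test needs known orthologs from >= 2 other species")

    species = sorted(by_species)
    lcas = {s: tree.lca([sp, s]) for s in species}
    distinct = len(set(lcas.values())) > 1

    pairs = [(a, b) for i, a in enumerate(species) for b in species[i + 1:]]
    # most divergent pair; lexicographically smallest on ties
    pair = min(pairs, key=lambda p: (-tree.divergence_time(*p), p))
    d2 = tree.divergence_time(*pair)
    value2 = global_identity(by_species[pair[0]][1].seq,
                             by_species[pair[1]][1].seq).identity_pct

    if distinct:
        nearer = min(species, key=lambda s: (tree.divergence_time(sp, s), s))
        return ConservationTestInput(
            candidate_species=sp, mode="distinct_lca",
            d1=tree.divergence_time(sp, nearer), d2=d2,
            value1=by_species[nearer][0], value2=value2,
            nearer_known=nearer, known_pair=pair)
    # same LCA: D1 identical for every known; Value1 = best identity to a
    # calibration-pair member (benefit of the doubt favors 'gene')
    d1 = tree.divergence_time(sp, pair[0])
    value1 = max(by_species[pair[0]][0], by_species[pair[1]][0])
    nearer = max(pair, key=lambda s: by_species[s][0])
    return ConservationTestInput(
        candidate_species=sp, mode="same_lca", d1=d1, d2=d2,
        value1=value1, value2=value2, nearer_known=nearer, known_pair=pair)
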