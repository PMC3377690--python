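"""Translated homology search: find candidate orthologous loci in a genome.

Given a reference protein, each genome sequence is scanned in all six reading
frames with exact k-mer protein seeds extended into ungapped locally-optimal
segments (BLOSUM62).  Hits on one chromosome/strand that are collinear in
both genome and protein order are chained into locus candidates, and the
spanned DNA (plus flanks) is extracted for gene prediction and the
nucleotide-level scan.  Stop codons in a frame score as strong mismatches but
do not terminate extension, so pseudogenized loci remain findable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import blosum62, reverse_complement, translate
from .errors import DomainError
from .formats_io import SequenceRecord

__all__ = [
    "SearchParams", "TranslatedHit", "LocusCandidate", "Locus",
    "six_frame_translate", "translated_search", "chain_hits", "extract_locus",
]

STOP_SCORE = -6.0  # in-frame stop vs any reference residue


@dataclass(frozen=True)
class SearchParams:
    seed_k: int = 4
    min_score: float = 50.0
    xdrop: float = 20.0
    max_gap: int = 50000
    max_protein_overlap: int = 5
    max_genome_overlap: int = 15


@dataclass(frozen=True)
class TranslatedHit:
    """One ungapped translated segment, in plus-strand genome coordinates."""

    chrom: str
    strand: str
    genome_start: int
    genome_end: int
    frame: int
    protein_start: int
    protein_end: int
    score: float
    hit_protein: str  # translation of the genomic segment, 5'->3' on the hit strand

    def __post_init__(self):
        if self.genome_end <= self.genome_start:
            raise DomainError("empty hit interval")

    @property
    def transcript_start(self) -> int:
        """Genome coordinate in transcript orientation (for chaining)."""
        return self.genome_start if self.strand == "+" else -self.genome_end

    @property
    def transcript_end(self) -> int:
        return self.genome_end if self.strand == "+" else -self.genome_start


@dataclass
class LocusCandidate:
    """A chained, collinear set of hits on one chromosome and strand."""

    hits: list  # of TranslatedHit, sorted 5'->3' in transcript orientation
    total_score: float = 0.0

    def __post_init__(self):
        self.hits = sorted(self.hits, key=lambda h: h.transcript_start)
        self.total_score = sum(h.score for h in self.hits)

    @property
    def chrom(self) -> str:
        return self.hits[0].chrom

    @property
    def strand(self) -> str:
        return self.hits[0].strand

    @property
    def genome_span(self) -> tuple[int, int]:
        return (min(h.genome_start for h in self.hits),
                max(h.genome_end for h in self.hits))

    @property
    def concatenated_protein(self) -> str:
        return "".join(h.hit_protein for h in self.hits)


@dataclass(frozen=True)
class Locus:
    """Extracted DNA segment with the mapping back to genome coordinates."""

    record: SequenceRecord
    chrom: str
    strand: str
    plus_start: int  # plus-strand genome coordinate of the extracted slice
    plus_end: int

    def to_genome(self, local: int) -> int:
        """Map a local coordinate of the extracted sequence to the genome."""
        if not 0 <= local <= len(self.record.seq):
            raise DomainError("local coordinate outside locus")
        if self.strand == "+":
            return self.plus_start + local
        return self.plus_end - local


def six_frame_translate(dna: str) -> dict[tuple[str, int], str]:
    """Translate all six frames; keys are (strand, frame offset 0/1/2)."""
    out = {}
    rc = reverse_complement(dna)
    for frame in range(3):
        out[("+", frame)] = translate(dna[frame:])
        out[("-", frame)] = translate(rc[frame:])
    return out


def _segment_scores(ref: str, frame_prot: str, diag: int,
                    matrix) -> tuple[int, int, list[float]]:
    """Per-position scores along one diagonal (ref pos p vs frame pos p+diag)."""
    lo = max(0, -diag)
    hi = min(len(ref), len(frame_prot) - diag)
    scores = []
    for p in range(lo, hi):
        aa_r, aa_h = ref[p], frame_prot[p + diag]
        if aa_h == "*":
            scores.append(STOP_SCORE)
        else:
            try:
                scores.append(float(matrix[aa_r, aa_h]))
            except (KeyError, IndexError):
                scores.append(-1.0)
    return lo, hi, scores


def _best_segment(scores: list[float]) -> tuple[int, int, float]:
    """Maximal-sum contiguous segment (Kadane); leftmost on ties."""
    best_s = best_e = 0
    best = float("-inf")
    cur_start = 0
    cur = 0.0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = s
            cur_start = i
        else:
            cur += s
        if cur > best:
            best, best_s, best_e = cur, cur_start, i + 1
    return best_s, best_e, best


def translated_search(reference: SequenceRecord, genome: Sequence[SequenceRecord],
                      params: SearchParams = SearchParams()) -> list[TranslatedHit]:
    """Seed-and-extend search of a protein against DNA, six frames.

    Returns hits above ``params.min_score`` sorted by descending score.
    """
    ref = reference.seq
    k = params.seed_k
    if len(ref) < k:
        raise DomainError(f"reference shorter than seed size {k}")
    matrix = blosum62()
    seeds: dict[str, list[int]] = {}
    for p in range(len(ref) - k + 1):
        seeds.setdefault(ref[p:p + k], []).append(p)

    hits: list[TranslatedHit] = []
    for chrom_rec in genome:
        dna = chrom_rec.seq
        L = len(dna)
        frames = six_frame_translate(dna)
        for (strand, frame), prot in frames.items():
            diags: set[int] = set()
            for q in range(len(prot) - k + 1):
                for p in seeds.get(prot[q:q + k], ()):
                    diags.add(q - p)
            for diag in sorted(diags):
                lo, hi, scores = _segment_scores(ref, prot, diag, matrix)
                if lo >= hi:
                    continue
                s, e, score = _best_segment(scores)
                if score < params.min_score:
                    continue
                p_start, p_end = lo + s, lo + e
                q_start, q_end = p_start + diag, p_end + diag
                nt_start = frame + 3 * q_start  # on the hit strand
                nt_end = frame + 3 * q_end
                if strand == "+":
                    g_start, g_end = nt_start, nt_end
                else:
                    g_start, g_end = L - nt_end, L - nt_start
                hits.append(TranslatedHit(
                    chrom=chrom_rec.id, strand=strand,
                    genome_start=g_start, genome_end=g_end, frame=frame,
                    protein_start=p_start, protein_end=p_end, score=score,
                    hit_protein=prot[q_start:q_end]))
    hits.sort(key=lambda h: (-h.score, h.chrom, h.strand, h.genome_start))
    return _deduplicate(hits)


def _deduplicate(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Drop lower-scoring hits nested inside an already-kept genomic span."""
    kept: list[TranslatedHit] = []
    for h in hits:
        nested = any(k.chrom == h.chrom and k.strand == h.strand
                     and k.genome_start <= h.genome_start
                     and h.genome_end <= k.genome_end
                     for k in kept)
        if not nested:
            kept.append(h)
    return kept


def _compatible(chain: list[TranslatedHit], h: TranslatedHit,
                params: SearchParams) -> bool:
    if not chain:
        return True
    if h.chrom != chain[0].chrom or h.strand != chain[0].strand:
        return False
    order = sorted(chain + [h], key=lambda x: x.transcript_start)
    for a, b in zip(order, order[1:]):
        gap = b.transcript_start - a.transcript_end
        if gap > params.max_gap or gap < -params.max_genome_overlap:
            return False
        if b.protein_start < a.protein_start:  # protein order must follow
            return False
        if a.protein_end - b.protein_start > params.max_protein_overlap:
            return False
    return True


def chain_hits(hits: Sequence[TranslatedHit],
               params: SearchParams = SearchParams()) -> list[LocusCandidate]:
    """Greedy chaining of compatible hits; each hit joins exactly one chain."""
    remaining = sorted(hits, key=lambda h: (-h.score, h.chrom, h.strand,
                                            h.genome_start))
    candidates: list[LocusCandidate] = []
    used: set[int] = set()
    for i, seed in enumerate(remaining):
        if i in used:
            continue
        used.add(i)
        chain = [seed]
        changed = True
        while changed:
            changed = False
            for j, h in enumerate(remaining):
                if j in used:
                    continue
                if _compatible(chain, h, params):
                    chain.append(h)
                    used.add(j)
                    changed = True
        candidates.append(LocusCandidate(chain))
    candidates.sort(key=lambda c: -c.total_score)
    return candidates


def extract_locus(genome: Sequence[SequenceRecord], candidate: LocusCandidate,
                  flank: int = 5000) -> Locus:
    """Extract the candidate's DNA span plus flanks (reverse-complemented for
    minus-strand candidates), clamped to chromosome ends."""
    chrom_rec = next((g for g in genome if g.id == candidate.chrom), None)
    if chrom_rec is None:
        raise DomainError(f"chromosome {candidate.chrom!r} not in genome")
    lo, hi = candidate.genome_span
    start = max(0, lo - flank)
    end = min(len(chrom_rec.seq), hi + flank)
    seq = chrom_rec.seq[start:end]
    if candidate.strand == "-":
        seq = reverse_complement(seq)
    rec = SequenceRecord(
        id=f"{candidate.chrom}:{start + 1}-{end}({candidate.strand})",
        species=chrom_rec.species, seq=seq, kind="dna")
    return Locus(rec, candidate.chrom, candidate.strand, start, end)
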