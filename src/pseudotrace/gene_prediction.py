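"""Reference-guided gene prediction from a DNA locus.

The predictor aligns a reference protein to a genomic locus with a spliced
dynamic program: codons are consumed three nucleotides at a time, introns may
be entered only at canonical GT..AG boundaries (length >= MIN_INTRON, placed
between codons), and candidate exon codons that are stop codons are excluded
outright.  The optimum is therefore forced to avoid nonsense codons by
trimming the prediction, splicing them into introns, or shifting the aligned
segment — degraded pseudogene loci yield shortened predictions or none at
all.  The predicted protein is exactly the translation of the selected exon
codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .alignment import blosum62, translate
from .errors import DomainError
from .formats_io import ExonAnnotation, SequenceRecord
from .homology_search import Locus

__all__ = ["PredictParams", "ProteinPrediction", "predict_protein",
           "find_annotated_gene_at_locus", "self_score"]

MIN_INTRON = 20
NEG = -1e9    # effectively -inf for alignment scores
BIG = 1e12    # group offset for the reset-at-stop prefix max

_AA = "ACDEFGHIKLMNPQRSTVWYX*"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}

_MATRIX: Optional[np.ndarray] = None


def _matrix() -> np.ndarray:
    global _MATRIX
    if _MATRIX is None:
        m = blosum62()
        arr = np.full((len(_AA), len(_AA)), -4.0)
        for a in _AA:
            for b in _AA:
                try:
                    arr[_AA_INDEX[a], _AA_INDEX[b]] = float(m[a, b])
                except (KeyError, IndexError):
                    pass
        _MATRIX = arr
    return _MATRIX


@dataclass
class PredictParams:
    gap_codon: float = -12.0       # per skipped reference residue / inserted codon
    intron_penalty: float = -15.0  # flat cost of opening one intron
    min_score_frac: float = 0.40   # of the reference self-score


@dataclass
class ProteinPrediction:
    """Best protein predicted from a locus, with its exon structure."""

    protein: str
    exons: list            # locus-local (start, end) intervals, 5'->3'
    splice_sites: list     # (donor_dinuc, acceptor_dinuc) per junction
    score: float
    frame_per_exon: list   # phase of each exon (0 under the between-codon model)
    ref_start: int         # first reference residue covered (0-based)
    ref_end: int


def self_score(protein: str) -> float:
    """BLOSUM62 score of a protein against itself (no gaps)."""
    mat = _matrix()
    return float(sum(mat[i, i] for i in
                     (_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in protein)))


def _chain_with_resets(values: np.ndarray, barrier: np.ndarray,
                       step_cost: float) -> np.ndarray:
    """H[t] = max(v[t], H[t-1] + step_cost), resetting to v[t] at barriers.

    Vectorized via a grouped prefix max: in the gauge u = H - step_cost*t the
    recurrence is a running max that restarts whenever a barrier position is
    reached (a chain may start at a barrier but not pass through one).
    """
    t = np.arange(len(values), dtype=float)
    w = values - step_cost * t
    g = np.cumsum(barrier).astype(float)
    u = np.maximum.accumulate(w + g * BIG) - g * BIG
    return np.maximum(values, u + step_cost * t)


def predict_protein(locus, reference: SequenceRecord,
                    params: PredictParams = PredictParams()
                    ) -> Optional[ProteinPrediction]:
    """Predict the protein most similar to the reference from a DNA locus.

    ``locus`` may be a Locus, a SequenceRecord or a plain DNA string.
    Returns None when the best spliced alignment scores below
    ``params.min_score_frac`` x reference self-score.
    """
    if isinstance(locus, Locus):
        dna = locus.record.seq
    elif isinstance(locus, SequenceRecord):
        dna = locus.seq
    else:
        dna = str(locus)
    if len(dna) < 3:
        raise DomainError("locus shorter than one codon")
    ref = reference.seq
    m, n = len(ref), len(dna)
    mat = _matrix()
    gap, ipen = params.gap_codon, params.intron_penalty

    # codon ending at position j is dna[j-3:j]
    codon_aa = np.zeros(n + 1, dtype=np.int64)
    for j in range(3, n + 1):
        c = dna[j - 3:j]
        codon_aa[j] = (_AA_INDEX["X"] if "N" in c
                       else _AA_INDEX[str(Seq(c).translate())])
    stop_mask = np.zeros(n + 1, dtype=bool)
    stop_mask[3:] = codon_aa[3:] == _AA_INDEX["*"]

    is_donor = np.zeros(n + 1, dtype=bool)     # GT begins at position d
    is_acceptor = np.zeros(n + 1, dtype=bool)  # AG ends at position j
    for d in range(n - 1):
        if dna[d] == "G" and dna[d + 1] == "T":
            is_donor[d] = True
    for j in range(2, n + 1):
        if dna[j - 2] == "A" and dna[j - 1] == "G":
            is_acceptor[j] = True

    def in_row_passes(row: np.ndarray) -> np.ndarray:
        # alternate insertion chains and intron jumps (twice covers any
        # realistic op sequence between two consumed reference residues)
        for _ in range(2):
            for r in range(3):
                row[r::3] = _chain_with_resets(row[r::3], stop_mask[r::3], gap)
            donor_vals = np.where(is_donor, row + ipen, NEG)
            acc = np.maximum.accumulate(donor_vals)
            jump = np.full(n + 1, NEG)
            if n + 1 > MIN_INTRON:
                jump[MIN_INTRON:] = acc[:-MIN_INTRON]
            row = np.where(is_acceptor, np.maximum(row, jump), row)
        return row

    ref_idx = np.array([_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in ref])
    H = np.zeros((m + 1, n + 1))
    H[0] = in_row_passes(np.zeros(n + 1))
    np.maximum(H[0], 0.0, out=H[0])
    sub_bar = np.where(stop_mask, NEG, 0.0)
    for i in range(1, m + 1):
        diag = np.full(n + 1, NEG)
        sub = mat[ref_idx[i - 1]][codon_aa]
        diag[3:] = H[i - 1][:-3] + sub[3:] + sub_bar[3:]
        row = np.maximum.reduce([diag, H[i - 1] + gap, np.zeros(n + 1)])
        H[i] = in_row_passes(row)

    best = float(H.max())
    if best <= 0 or best < params.min_score_frac * self_score(ref):
        return None
    i, j = divmod(int(np.argmax(H)), n + 1)  # first optimum: smallest (i, j)
    i_end = i

    codons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    while H[i][j] > 0:
        if (i > 0 and j >= 3 and not stop_mask[j]
                and H[i][j] == H[i - 1][j - 3] + mat[ref_idx[i - 1], codon_aa[j]]):
            codons.append((j - 3, j))
            i, j = i - 1, j - 3
        elif i > 0 and H[i][j] == H[i - 1][j] + gap:
            i -= 1
        elif j >= 3 and not stop_mask[j] and H[i][j] == H[i][j - 3] + gap:
            codons.append((j - 3, j))
            j -= 3
        else:
            hit = False
            if is_acceptor[j]:
                for d in range(j - MIN_INTRON, -1, -1):
                    if is_donor[d] and H[i][j] == H[i][d] + ipen:
                        introns.append((d, j))
                        j = d
                        hit = True
                        break
            if not hit:
                break
    codons.reverse()
    introns.reverse()
    if not codons:
        return None

    exons: list[list[int]] = [[codons[0][0], codons[0][1]]]
    for s, e in codons[1:]:
        if exons[-1][1] == s:
            exons[-1][1] = e
        else:
            exons.append([s, e])
    exon_ivals = [(s, e) for s, e in exons]
    splice = [(dna[d:d + 2], dna[a - 2:a]) for d, a in introns]
    protein = translate("".join(dna[s:e] for s, e in exon_ivals))
    return ProteinPrediction(
        protein=protein, exons=exon_ivals, splice_sites=splice, score=best,
        frame_per_exon=[0] * len(exon_ivals), ref_start=i, ref_end=i_end)


def find_annotated_gene_at_locus(annotations: Sequence[ExonAnnotation],
                                 species: str, chrom: str,
                                 interval: tuple[int, int],
                                 excluded: set = frozenset()) -> Optional[str]:
    """Annotated gene (not excluded) overlapping the interval by >= 1 nt;
    largest overlap wins, ties broken by gene_id."""
    lo, hi = interval
    if hi <= lo:
        raise DomainError("empty query interval")
    best = None
    for ann in annotations:
        if ann.species != species or ann.chrom != chrom:
            continue
        if ann.gene_id in excluded:
            continue
        s, e = ann.span
        overlap = min(e, hi) - max(s, lo)
        if overlap >= 1:
            key = (-overlap, ann.gene_id)
            if best is None or key < best[0]:
                best = (key, ann.gene_id)
    return best[1] if best else None
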