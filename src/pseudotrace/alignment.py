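"""Shared sequence-alignment utilities.

Pairwise global alignment is delegated to Bio.Align.PairwiseAligner and
multiple alignment to the MAFFT binary (run with deterministic options); both
are standard steps, not the scientific core of this package.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from functools import lru_cache
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .errors import DomainError, PseudotraceError

__all__ = [
    "blosum62", "global_align", "mafft_msa",
    "translate", "reverse_complement", "back_translate",
    "STOP_CODONS", "CODON_OF",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

# most-frequent human codon per amino acid (deterministic back-translation)
CODON_OF = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    "X": "NNN", "*": "TAA",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@lru_cache(maxsize=1)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


def translate(dna: str) -> str:
    """Translate a DNA string (standard code, '*' for stops, 'X' for N-codons).

    Trailing incomplete codons are dropped.
    """
    n = len(dna) - len(dna) % 3
    out = []
    for i in range(0, n, 3):
        codon = dna[i:i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def back_translate(protein: str) -> str:
    """Deterministic back-translation using most-frequent human codons."""
    return "".join(CODON_OF[aa] for aa in protein)


@lru_cache(maxsize=4)
def _aligner(open_gap: float, extend_gap: float) -> PairwiseAligner:
    a = PairwiseAligner()
    a.substitution_matrix = blosum62()
    a.open_gap_score = open_gap
    a.extend_gap_score = extend_gap
    a.mode = "global"
    return a


def global_align(a: str, b: str, open_gap: float = -10.0,
                 extend_gap: float = -0.5) -> tuple[float, str, str]:
    """Needleman–Wunsch global alignment with affine gaps, end gaps penalized.

    A gap of length L scores ``open_gap + (L-1) * extend_gap``.  Returns
    (score, gapped_a, gapped_b) for the first (deterministic) optimal
    traceback.
    """
    if not a or not b:
        raise DomainError("global_align requires non-empty sequences")
    aligner = _aligner(open_gap, extend_gap)
    aln = aligner.align(a, b)[0]
    rows = str(aln).splitlines()
    # format: target / pipes / query blocks; reconstruct from indices instead
    ga, gb = _gapped_from_alignment(aln, a, b)
    return float(aln.score), ga, gb


def _gapped_from_alignment(aln, a: str, b: str) -> tuple[str, str]:
    ga, gb = [], []
    blocks_a, blocks_b = aln.aligned
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        # unaligned stretch before this block
        da, db = sa - pa, sb - pb
        ga.append(a[pa:sa] + "-" * db)
        gb.append("-" * da + b[pb:sb])
        ga.append(a[sa:ea])
        gb.append(b[sb:eb])
        pa, pb = ea, eb
    da, db = len(a) - pa, len(b) - pb
    ga.append(a[pa:] + "-" * db)
    gb.append("-" * da + b[pb:])
    return "".join(ga), "".join(gb)


def mafft_msa(seqs: list[tuple[str, str]], kind: str = "protein") -> list[tuple[str, str]]:
    """Multiple sequence alignment via MAFFT (FFT-NS-2, deterministic).

    ``seqs`` is a list of (name, sequence); returns (name, gapped sequence)
    in input order.
    """
    if len(seqs) < 2:
        raise DomainError("MSA requires at least 2 sequences")
    if shutil.which("mafft") is None:  # pragma: no cover - environment guard
        raise PseudotraceError("mafft binary not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        with open(fin, "w") as fh:
            for i, (_, seq) in enumerate(seqs):
                fh.write(f">s{i}\n{seq}\n")
        args = ["mafft", "--retree", "2", "--maxiterate", "0", "--quiet",
                "--anysymbol"]
        if kind == "dna":
            args += ["--nuc"]
        else:
            args += ["--amino"]
        res = subprocess.run(args + [str(fin)], capture_output=True, text=True)
        if res.returncode != 0:  # pragma: no cover
            raise PseudotraceError(f"mafft failed: {res.stderr[:500]}")
    rows: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            rows[name] = ""
        elif name is not None:
            rows[name] += line.strip()
    out = []
    for i, (orig_name, _) in enumerate(seqs):
        if f"s{i}" not in rows:  # pragma: no cover
            raise PseudotraceError(f"mafft dropped sequence {orig_name!r}")
        out.append((orig_name, rows[f"s{i}"].upper()))
    return out
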