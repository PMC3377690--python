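"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (protein/DNA), Newick/NHX (trees), a tab-delimited exon table,
YAML run configuration and the JSON study report.  Coordinates are 0-based
half-open internally and 1-based closed in human-readable output.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .errors import ConsistencyError, DomainError, FormatError
from .species_tree import SpeciesTree, TreeNode, node_to_newick, parse_newick_node

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = set("ACGTN")

__all__ = [
    "SequenceRecord", "ExonAnnotation", "RunConfig",
    "read_fasta", "write_fasta", "read_species_tree",
    "read_exon_table", "write_exon_table",
    "load_config", "write_annotated_tree", "read_annotated_tree",
    "write_report_json",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry; ``species`` is parsed from the header (species|gene)."""

    id: str
    species: str
    seq: str
    kind: str  # "protein" | "dna"

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.seq):
            if ch not in alphabet:
                raise FormatError(
                    f"record {self.id!r}: illegal {self.kind} residue "
                    f"{ch!r} at position {pos + 1}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ExonAnnotation:
    """Exon structure of one annotated gene, in plus-strand genomic coordinates.

    ``exons`` are 0-based half-open (start, end) intervals sorted 5'->3' in
    transcript orientation: ascending genomic coordinate on '+', descending
    on '-'.
    """

    gene_id: str
    species: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise FormatError(f"{self.gene_id}: empty exon interval ({s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        expect = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if tuple(self.exons) != expect:
            raise FormatError(
                f"{self.gene_id}: exons not in transcript orientation")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min start, max end) over all exons."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


_DEFAULT_THRESHOLDS = {
    "test1_length_pct": 60.0,
    "test1_similarity_pct": 50.0,
    "test3_max_divergence_pct": 60.0,
    "chain_max_gap_nt": 50000,
    "locus_flank_nt": 5000,
    "compaction_flank_nt": 20,
    "search_min_score": 50.0,
    "search_seed_k": 4,
    "predict_min_score_frac": 0.40,
    "phase1_min_identity_pct": 30.0,
    "phase1_top_n": 3,
    "candidate_cap": 5,
}


@dataclass
class RunConfig:
    """Run configuration: ancestor of interest, mode and numeric thresholds."""

    ancestor: str
    mode: str = "complete"  # "simple" | "complete"
    thresholds: dict = field(default_factory=dict)
    excluded_gene_ids: set = field(default_factory=set)
    seed: int = 0
    force_species_tree: bool = True
    scan_subfamilies: bool = False
    header_separator: str = "|"

    def __post_init__(self):
        if self.mode not in ("simple", "complete"):
            raise FormatError(f"unknown mode {self.mode!r}")
        merged = dict(_DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key in ("test1_length_pct", "test1_similarity_pct",
                    "test3_max_divergence_pct"):
            v = self.thresholds[key]
            if not 0 <= v <= 100:
                raise FormatError(f"threshold {key}={v} outside [0,100]")
        self.excluded_gene_ids = set(self.excluded_gene_ids)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "ancestor" not in data:
        raise FormatError("config missing required key 'ancestor'")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, kind: str, separator: str = "|") -> list[SequenceRecord]:
    """Read a FASTA file; header is ``species<sep>gene_id`` (species first).

    Headers without the separator yield species == id (single-token headers
    are permitted for query sequences).
    """
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    chunks: list[str] = []
    seen: set[str] = set()

    def flush():
        if header is None:
            return
        seq = "".join(chunks).upper()
        if separator in header:
            species, _, _rest = header.partition(separator)
        else:
            species = header
        if header in seen:
            raise FormatError(f"duplicate FASTA id {header!r}")
        seen.add(header)
        records.append(SequenceRecord(id=header, species=species, seq=seq, kind=kind))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip().split()[0]
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Species tree

def read_species_tree(path) -> SpeciesTree:
    """Read, and validate as binary + ultrametric, a Newick species tree."""
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty tree file")
    return SpeciesTree.from_newick(text)


# ---------------------------------------------------------------------------
# Exon table (tab-delimited: gene_id, species, chrom, strand, start-end,...)

def read_exon_table(path) -> list[ExonAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 tab-separated "
                                  f"fields, got {len(parts)}")
            gene_id, species, chrom, strand, exon_str = parts
            exons = []
            for token in exon_str.split(","):
                m = re.fullmatch(r"(\d+)-(\d+)", token)
                if not m:
                    raise FormatError(f"{path}:{lineno}: bad exon token {token!r}")
                # 1-based closed on disk -> 0-based half-open in memory
                exons.append((int(m.group(1)) - 1, int(m.group(2))))
            out.append(ExonAnnotation(gene_id, species, chrom, strand, tuple(exons)))
    return out


def write_exon_table(annotations: Iterable[ExonAnnotation], path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            exon_str = ",".join(f"{s + 1}-{e}" for s, e in ann.exons)
            fh.write("\t".join([ann.gene_id, ann.species, ann.chrom,
                                ann.strand, exon_str]) + "\n")


# ---------------------------------------------------------------------------
# Annotated species tree (NHX) + JSON report

_NHX_SAFE = re.compile(r"[^A-Za-z0-9_.@+|-]")


def _nhx_escape(text: str) -> str:
    return _NHX_SAFE.sub("_", str(text))


def _mutation_token(m) -> str:
    """Compact mutation encoding kind@exon@pos@detail (NHX-safe)."""
    detail = _nhx_escape(m.detail) if m.detail else "."
    return f"{m.kind}@{m.exon_index}@{m.position}@{detail}"


def write_annotated_tree(tree: SpeciesTree, report, path) -> None:
    """Write the species tree with per-leaf states and per-branch events (NHX).

    ``report`` must expose ``leaf_states`` (species -> state), ``events``
    (objects with .branch (parent, child), .event, .supporting_mutations) and
    ``birth_node``.
    """
    by_child: dict[str, list] = {}
    for ev in report.events:
        parent, child = ev.branch
        if parent not in tree or child not in tree:
            raise ConsistencyError(f"event on unknown branch {ev.branch}")
        if tree.node(child).parent is None or tree.node(child).parent.name != parent:
            raise ConsistencyError(f"{parent}->{child} is not a branch of the tree")
        by_child.setdefault(child, []).append(ev)
    if report.birth_node is not None and report.birth_node not in tree:
        raise ConsistencyError(f"birth node {report.birth_node!r} not in tree")

    def comment(node: TreeNode) -> str:
        tags = []
        if node.is_leaf and node.name in report.leaf_states:
            tags.append(f"S={report.leaf_states[node.name]}")
        for ev in by_child.get(node.name, []):
            tags.append(f"E={ev.event}")
            for m in (ev.supporting_mutations or []):
                tags.append(f"M={_mutation_token(m)}")
        if report.birth_node == node.name:
            tags.append("B=Y")
        if not tags:
            return ""
        return "[&&NHX:" + ":".join(tags) + "]"

    Path(path).write_text(node_to_newick(tree.root, comment_for=comment) + "\n")


def read_annotated_tree(path):
    """Round-trip reader for write_annotated_tree output.

    Returns (SpeciesTree, leaf_states, events, birth_node) where events is a
    list of EventPlacement objects.
    """
    from .event_synthesis import EventPlacement
    from .nucleotide_scan import Mutation

    text = Path(path).read_text().strip()
    # split NHX comments out, parse the bare newick, then re-attach by name
    comments: dict[int, str] = {}
    bare = []
    i = 0
    order = []
    pat = re.compile(r"\[&&NHX:([^\]]*)\]")
    pos = 0
    stripped = ""
    tag_for_prefix: list[tuple[int, str]] = []
    for m in pat.finditer(text):
        stripped += text[pos:m.start()]
        tag_for_prefix.append((len(stripped), m.group(1)))
        pos = m.end()
    stripped += text[pos:]
    tree = SpeciesTree.from_newick(stripped)

    # map each tag to the node whose serialization ends at that offset: the
    # token immediately before the tag is "name:length" — recover the name.
    leaf_states: dict[str, str] = {}
    events: list = []
    birth = None
    for offset, tag in tag_for_prefix:
        before = stripped[:offset]
        m = re.search(r"([A-Za-z0-9_.@|-]+)(?::[0-9.eE+-]+)?$", before)
        if not m:
            raise FormatError(f"{path}: cannot locate node for NHX tag {tag!r}")
        name = m.group(1)
        node = tree.node(name)
        current_event = None
        for item in tag.split(":"):
            key, _, val = item.partition("=")
            if key == "S":
                leaf_states[name] = val
            elif key == "E":
                parent = node.parent.name if node.parent else None
                current_event = EventPlacement(branch=(parent, name), event=val,
                                               supporting_mutations=[])
                events.append(current_event)
            elif key == "M":
                kind, exon, posn, detail = val.split("@")
                mut = Mutation(kind=kind, exon_index=int(exon),
                               position=int(posn),
                               detail="" if detail == "." else detail,
                               branch=current_event.branch if current_event else None)
                current_event.supporting_mutations.append(mut)
            elif key == "B":
                birth = name
    return tree, leaf_states, events, birth


def write_report_json(report_dict: dict, path) -> None:
    """Write the machine-readable study report (deterministic formatting)."""
    with open(path, "w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
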