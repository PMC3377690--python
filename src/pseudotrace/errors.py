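"""Exception hierarchy shared across the pipeline."""


class PseudotraceError(Exception):
    """Base class for all package errors."""


class FormatError(PseudotraceError):
    """Malformed input file (FASTA, Newick, exon table, config)."""


class StructureError(PseudotraceError):
    """Tree violates a structural requirement (e.g. polytomy)."""


class ValidationError(PseudotraceError):
    """Input parsed but fails a semantic check (e.g. non-ultrametric tree)."""


class LookupError_(PseudotraceError):
    """Unknown node/species/gene name."""


class DomainError(PseudotraceError):
    """Operation called outside its domain (bad arguments)."""


class InsufficientDataError(PseudotraceError):
    """Too few sequences/taxa to run a test; caller should fall back."""


class ConsistencyError(PseudotraceError):
    """Internal cross-reference broken (event on unknown branch etc.)."""
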