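"""Exception hierarchy."""


class PhyloratesError(Exception):
    """Base class for all package errors."""


class FormatError(PhyloratesError):
    """Malformed input file (FASTA, Newick, partition sidecar, matrix file)."""


class BindError(PhyloratesError):
    """Alignment / tree / partition sets that do not fit together."""


class DomainError(PhyloratesError, ValueError):
    """Argument outside its mathematical domain (negative rate, bad shape, ...)."""
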