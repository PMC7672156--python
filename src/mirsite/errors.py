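"""Exception hierarchy shared across the package."""


class MirsiteError(Exception):
    """Base class for all package errors."""


class AlphabetError(MirsiteError, ValueError):
    """A sequence contains a character outside the accepted RNA alphabet."""


class FastaError(MirsiteError, ValueError):
    """Malformed FASTA input (empty file, duplicate ids, empty record)."""


class AnnotationError(MirsiteError, ValueError):
    """Invalid or missing CDS annotation for a transcript."""


class ContractError(MirsiteError, ValueError):
    """A call violated an operation precondition."""
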