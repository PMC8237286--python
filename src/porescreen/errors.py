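"""Exception hierarchy shared across the package."""


class PorescreenError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(PorescreenError):
    """Input is not valid FASTA/FASTQ."""


class AlphabetError(PorescreenError):
    """A sequence contains a symbol outside the supported DNA alphabet."""


class IndexFormatError(PorescreenError):
    """An index file is corrupt, truncated, or has the wrong magic/version."""


class CapabilityError(PorescreenError):
    """The index mode does not support the requested query (e.g. MS on a
    PML-only index, which retains neither SA samples nor the text)."""


class InsufficientDataError(PorescreenError):
    """Too few bases to form a single classification window; the decision
    is deferred."""


class ParameterError(PorescreenError):
    """Invalid configuration or simulation parameter."""
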