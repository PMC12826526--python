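"""Exception hierarchy shared by all looplink modules."""


class LoopLinkError(Exception):
    """Base class for all looplink errors."""


class FormatError(LoopLinkError):
    """A file does not conform to its expected format (FASTA, GML, ...)."""


class SchemaError(LoopLinkError):
    """A required column of a cross-link table is not mapped or missing."""


class ParseError(LoopLinkError):
    """A single row/field of an input table could not be parsed."""


class BoundsError(LoopLinkError):
    """A residue index falls outside the protein sequence."""


class ContractError(LoopLinkError):
    """A function precondition was violated by the caller."""


class ConvergenceError(LoopLinkError):
    """An iterative numerical solve failed to reach its tolerance."""


class ConfigError(LoopLinkError):
    """A run configuration file is invalid."""


class GenerationError(LoopLinkError):
    """The synthetic-chain generator could not place a residue."""
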