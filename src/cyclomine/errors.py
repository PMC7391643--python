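"""Exception hierarchy shared across the package."""


class CyclomineError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(CyclomineError):
    """Malformed FASTA input (bad header, no records where expected)."""


class DuplicateIdError(FastaParseError):
    """Two records in one file share an identifier."""


class AlphabetError(CyclomineError):
    """A sequence contains characters outside its declared alphabet."""


class ValidationError(CyclomineError):
    """A parsed table or record violates a structural invariant."""


class ConfigError(CyclomineError):
    """A simulation or run configuration is internally inconsistent."""


class NotAPrecursorError(CyclomineError):
    """A protein lacks the cysteine cluster required of a cyclotide precursor."""


class PatternSyntaxError(CyclomineError):
    """A PROSITE-syntax pattern fails to parse.

    ``position`` holds the character offset of the offending token.
    """

    def __init__(self, message: str, position: int = -1):
        super().__init__(message)
        self.position = position
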