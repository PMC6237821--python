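"""Exception hierarchy for the package."""


class Mfn2sevError(Exception):
    """Base class for all package errors."""


class ParseError(Mfn2sevError, ValueError):
    """Malformed input text (mutation label, ordering chain, data file)."""


class ValidationError(Mfn2sevError, ValueError):
    """Well-formed input that violates a domain constraint."""


class StructureError(Mfn2sevError, ValueError):
    """Unreadable or inconsistent coordinate input."""
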