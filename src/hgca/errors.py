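"""Exception hierarchy shared by all modules."""


class HgcaError(Exception):
    """Base class for every error raised by this package."""


class ValidationError(HgcaError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(HgcaError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ProbeLookupError(HgcaError, KeyError):
    """A requested probe set is not present in the queried structure."""
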