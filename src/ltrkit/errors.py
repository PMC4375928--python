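"""Exception hierarchy shared across the toolkit."""


class LtrkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(LtrkitError):
    """A stream violates the syntax of its declared format."""


class ValidationError(LtrkitError):
    """Parsed data violates a semantic invariant (coordinates, alphabet, ids)."""


class InputError(LtrkitError):
    """An operation received arguments outside its contract."""


class DegenerateTableError(InputError):
    """A contingency table has a zero margin, so the test is undefined."""
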