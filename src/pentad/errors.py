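"""Exception hierarchy shared by all pentad modules."""


class PentadError(Exception):
    """Base class for all errors raised by this package."""


class InputError(PentadError):
    """A required input file is absent or unreadable."""


class ValidationError(PentadError):
    """An input or argument violates a documented contract."""
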