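"""Exception hierarchy shared across the package."""


class SojasweepError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SojasweepError):
    """Malformed or unsupported input file content."""


class InvariantError(SojasweepError):
    """A domain-type invariant or operation precondition was violated."""
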