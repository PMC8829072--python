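"""Exception hierarchy shared by all isvor modules."""


class IsvorError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(IsvorError, ValueError):
    """An argument violates a documented precondition (rate out of range,
    odd ring-lattice degree, unknown variant name, ...)."""


class FormatError(IsvorError, ValueError):
    """A file or serialized object does not match its documented schema."""


class NumericalError(IsvorError, RuntimeError):
    """An integrator or numerical routine failed; the message carries the
    solver diagnostic."""
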