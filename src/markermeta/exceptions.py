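"""Exception hierarchy shared across the package.

``ValidationError`` marks malformed or inconsistent *input* (CLI exit code 2);
``DegenerateModelError`` marks inputs that are formally valid but put a model
outside its domain, e.g. an SROC slope with |b| >= 1 (CLI exit code 3).
"""


class MarkerMetaError(Exception):
    """Base class for all package errors."""


class ValidationError(MarkerMetaError):
    """Input data violate a documented precondition or invariant."""


class DegenerateModelError(MarkerMetaError):
    """A fitted model is degenerate and cannot be used downstream."""
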