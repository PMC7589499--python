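"""Typed exceptions raised across the pipeline.

Every validation failure raises one of these; inputs that violate a
container invariant are never silently coerced.
"""


class ConsensusDEError(Exception):
    """Base class for all package errors."""


class FormatError(ConsensusDEError):
    """A file does not conform to its expected dialect."""


class DesignError(ConsensusDEError):
    """A study design violates the nested replicate structure."""


class ParameterError(ConsensusDEError):
    """An invalid configuration or function parameter."""


class NormalizationError(ConsensusDEError):
    """Size factors cannot be computed (e.g. no gene positive everywhere)."""


class DomainError(ConsensusDEError):
    """A numeric argument lies outside its mathematical domain."""


class InputError(ConsensusDEError):
    """Inconsistent inputs to an analysis step (e.g. DE set not in background)."""
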