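"""Exception hierarchy.

All package errors derive from :class:`FluolungError` so callers can catch
one base class; subclasses also derive from the matching builtin
(``ValueError``/``OSError``) where that is the conventional behaviour.
"""


class FluolungError(Exception):
    """Base class for all fluolung errors."""


class InvalidParameterError(FluolungError, ValueError):
    """A physical or numerical parameter is outside its valid domain."""


class ConstraintViolationError(FluolungError, ValueError):
    """A derived acquisition constraint (e.g. TE >= TE_min) is violated."""


class InfeasibleSamplingError(FluolungError, ValueError):
    """The requested undersampling pattern cannot be constructed."""


class DivergenceError(FluolungError, RuntimeError):
    """An iterative solver diverged; carries diagnostics in ``details``."""

    def __init__(self, msg: str, details: dict | None = None):
        super().__init__(msg)
        self.details = details or {}


class FormatError(FluolungError, OSError):
    """A file does not conform to the expected on-disk layout."""
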