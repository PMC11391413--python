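"""Exception hierarchy shared across the package."""


class CspfitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CspfitError, ValueError):
    """Malformed or out-of-domain input (bad concentrations, unknown nucleus, ...)."""


class NumericalError(CspfitError, RuntimeError):
    """A solver or optimiser failed to converge; the message names the offending point."""


class UnderdeterminedError(CspfitError, ValueError):
    """Fewer observations than free parameters."""


class ComparisonError(CspfitError, ValueError):
    """Model comparison requested across fits on different observation sets."""
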