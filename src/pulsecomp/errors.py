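"""Exception hierarchy for pulsecomp.

Everything derives from :class:`PulsecompError` so callers can catch the
package's failures with a single except clause while still letting genuine
programming errors (TypeError etc.) propagate.
"""


class PulsecompError(Exception):
    """Base class for all pulsecomp errors."""


class InvalidInputError(PulsecompError, ValueError):
    """A precondition on user-supplied data or parameters is violated."""


class UndefinedPulsatilityError(InvalidInputError):
    """Pulsatility index requested for a waveform with non-positive mean flow."""


class UnreachablePulsePressureError(PulsecompError, RuntimeError):
    """Measured pulse pressure exceeds the Windkessel model's attainable range.

    The modeled pulse pressure is strictly decreasing in compliance with
    supremum R*(Qsyst - Qdias) at C -> 0+, so a measured PP at or above that
    bound has no positive-compliance solution.
    """

    def __init__(self, measured_pp: float, pp_supremum: float):
        self.measured_pp = measured_pp
        self.pp_supremum = pp_supremum
        super().__init__(
            f"measured PP {measured_pp:.4g} mmHg is not reachable: the "
            f"zero-compliance supremum of the modeled PP is {pp_supremum:.4g} mmHg"
        )


class ConvergenceError(PulsecompError, RuntimeError):
    """A solver or optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class InsufficientDataError(PulsecompError, ValueError):
    """Too few observations for the requested statistical comparison."""


class UndefinedCorrelationError(PulsecompError, ValueError):
    """Correlation requested on a constant (zero-variance) input."""


class DataFormatError(PulsecompError, ValueError):
    """Malformed input file; message carries file/line/field context."""
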