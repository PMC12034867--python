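"""Exception hierarchy shared across the pipeline stages."""


class RenalflowError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RenalflowError):
    """Invalid or infeasible configuration (regimes, model shapes, run config)."""


class DataError(RenalflowError):
    """Malformed or inconsistent data (schema violations, length mismatches)."""


class CalibrationError(RenalflowError):
    """Degenerate axis calibration (coincident reference points)."""


class SignalQualityError(RenalflowError):
    """Trace unusable for beat extraction (flat or no detectable upstroke)."""


class NumericalFailureError(RenalflowError):
    """Non-finite values encountered during optimization."""
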