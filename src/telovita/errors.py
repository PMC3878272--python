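"""Exception hierarchy shared across the package."""


class TelovitaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TelovitaError):
    """Invalid or internally inconsistent simulation/analysis configuration."""


class LadderCalibrationError(TelovitaError):
    """Molecular-weight ladder violates monotone size-vs-migration ordering."""


class MeasurementError(TelovitaError):
    """A densitometric or assay measurement is undefined (e.g. zero signal)."""


class CqUndeterminedError(TelovitaError):
    """Amplification curve never crosses the threshold in its exponential phase.

    Downstream code treats an undetermined Cq as censored, never as zero.
    """


class FitConvergenceError(TelovitaError):
    """Nonlinear fit failed after all restarts; carries the best partial fit."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class PairingError(TelovitaError):
    """Survival/telomere pairing could not be built (missing ages, wrong organ)."""


class InvalidModelError(TelovitaError):
    """A fitted model is outside its meaningful domain (e.g. non-positive slope)."""


class SchemaError(TelovitaError):
    """A delimited table does not conform to its declared schema."""
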