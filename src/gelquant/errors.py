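"""Exception hierarchy for the gel densitometry pipeline."""


class GelQuantError(Exception):
    """Base class for all package errors."""


class InputError(GelQuantError):
    """Unreadable or malformed input (file, config field, inconsistent arguments)."""


class DegenerateInputError(GelQuantError):
    """Structurally valid input that is too small or empty to process."""


class ParameterError(GelQuantError):
    """A tuning parameter outside its admissible range."""


class BoundsError(GelQuantError):
    """Row/column interval outside the data it indexes."""


class LaneDetectionError(GelQuantError):
    """Lane detection failed or disagrees with the expected lane count."""


class StateError(GelQuantError):
    """Operation applied to data in the wrong processing state."""


class FitError(GelQuantError):
    """Calibration or ladder fit cannot be computed from the given points."""


class DomainError(GelQuantError):
    """Numeric argument outside the mathematical domain of the operation."""


class SpecError(GelQuantError):
    """Inconsistent synthetic-gel specification."""
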