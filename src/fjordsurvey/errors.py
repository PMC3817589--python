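"""Exception hierarchy shared across the pipeline stages."""


class FjordSurveyError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FjordSurveyError):
    """Invalid generator or pipeline configuration (bad ranges, gapped presets...)."""


class FormatError(FjordSurveyError):
    """A delimited-text input is missing mandatory columns or is malformed."""


class DataError(FjordSurveyError):
    """Input rows are internally inconsistent (e.g. coral cover on zero substrate)."""


class GeometryError(FjordSurveyError):
    """Invalid camera model or frame geometry (non-positive range, FOV >= 180 deg)."""


class BreakSplitError(FjordSurveyError):
    """Above/below split at the requested break depth leaves one side empty."""


class CollinearityError(FjordSurveyError):
    """Regression design matrix is rank deficient."""
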