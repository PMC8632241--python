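"""Exception hierarchy shared across the pipeline."""


class ImmunoMRMError(Exception):
    """Base class for all errors raised by this package."""


class ReportFormatError(ImmunoMRMError):
    """A file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(ImmunoMRMError):
    """Well-formed input whose values violate an invariant."""


class ConfigurationError(ImmunoMRMError):
    """Missing or inconsistent analysis configuration (units, spike levels...)."""


class InsufficientReplicatesError(ValidationError):
    """Too few replicate measurements for the requested statistic."""
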