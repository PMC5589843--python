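"""Exception taxonomy shared across the pipeline stages."""


class LakeCouplingError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LakeCouplingError):
    """Inconsistent grid conventions, overlapping lake masks, bad config."""


class FormatError(LakeCouplingError):
    """Malformed input files (missing columns, unparseable rows)."""


class InsufficientDataError(LakeCouplingError):
    """A boosted-tree fit could not be supported at any admissible learning
    rate; callers eliminate the affected lake and record a reason code."""


class DegenerateFitError(LakeCouplingError):
    """Constant response, zero variance, or similar degenerate model input."""
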