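"""Exception hierarchy shared across the pipeline."""


class SzmirnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SzmirnetError):
    """A table does not conform to its documented format."""


class ValidationError(SzmirnetError):
    """Parsed data violates a documented invariant (e.g. tier nesting)."""


class ConfigError(SzmirnetError):
    """A configuration value is out of range or internally inconsistent."""


class EstimationError(SzmirnetError):
    """A statistical estimate is undefined for the given sample."""


class DependencyError(SzmirnetError):
    """A pipeline stage requires the output of a stage that was disabled."""
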