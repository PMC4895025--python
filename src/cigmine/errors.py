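"""Exception hierarchy shared across the package."""


class CigmineError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CigmineError):
    """A file does not conform to its documented grammar (names the offending line)."""


class ValidationError(CigmineError):
    """Structurally well-formed input violates a domain invariant."""


class CompletenessError(ValidationError):
    """A structure population is missing required (structure, domain, copy) records."""


class ConfigurationError(CigmineError):
    """An invalid parameter or configuration value."""


class UnsupportedVersionError(FormatError):
    """A serialized artifact declares a schema version this build cannot read."""


class DegenerateInstanceError(CigmineError):
    """An optimization instance is degenerate (e.g. all-zero gradient after retries)."""


class DegenerateControlError(CigmineError):
    """A statistical control variable is collinear with an analysed variable."""
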