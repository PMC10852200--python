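"""Exception hierarchy shared across idakit modules.

All idakit-raised errors derive from :class:`IdakitError` so callers (and the
CLI) can distinguish validation failures (exit code 1) from argument/usage
errors (exit code 2, raised by the argument parser itself).
"""


class IdakitError(Exception):
    """Base class for all idakit errors."""


class ScreenFormatError(IdakitError):
    """A screen or cap file is malformed (missing columns, empty, bad types)."""


class ScreenValidationError(IdakitError):
    """A parsed screen violates its invariants (e.g. conflicting duplicates)."""


class EmptySelectionError(IdakitError):
    """A filter or model-set intersection selected zero models."""


class ScreenLookupError(IdakitError):
    """A requested drug or concentration is absent from the screen."""


class CoverageError(IdakitError):
    """A model lacks a measurement for a treatment component it needs."""


class MetricDomainError(IdakitError):
    """A survival fraction left [0, inf); hazard ratios are not meaningful."""


class ConfigurationError(IdakitError):
    """An invalid simulation or treatment configuration."""


class ScreenValidationWarning(UserWarning):
    """Non-fatal data-quality finding (out-of-range efficacy, unused cap...)."""
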