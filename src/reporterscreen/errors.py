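"""Exception hierarchy shared across the package."""


class ReporterScreenError(Exception):
    """Base class for all package errors."""


class FormatError(ReporterScreenError):
    """An input file does not match the expected tabular schema."""


class IntegrityError(ReporterScreenError):
    """Parsed data violates a dataset invariant (duplicates, dangling ids)."""


class UndefinedStatisticError(ReporterScreenError):
    """A statistic is requested outside its domain (n < 2, zero mean, ...)."""


class InsufficientDataError(ReporterScreenError):
    """Too few usable observations to fit or summarize."""


class InsufficientControlsError(InsufficientDataError):
    """Fewer than two usable control wells on a plate/read."""


class ConfigError(ReporterScreenError):
    """A run or simulation configuration is internally inconsistent."""
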