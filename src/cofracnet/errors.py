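"""Exception hierarchy for cofracnet.

All package errors derive from :class:`CofracnetError` so callers (and the CLI)
can distinguish pipeline failures (exit 1) from usage errors (exit 2).
"""


class CofracnetError(Exception):
    """Base class for all cofracnet errors."""


class ConfigError(CofracnetError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(CofracnetError):
    """Malformed input file; the message includes the line number where known."""


class ProfileFitError(CofracnetError):
    """An elution profile has too few observed points to fit."""


class CalibrationError(CofracnetError):
    """Classifier calibration is impossible (no labeled pairs / too few complexes)."""


class UndefinedStatisticError(CofracnetError):
    """A statistic is undefined on this input (e.g. no annotated edges)."""
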