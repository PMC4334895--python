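"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation/configuration problems exit
with 2, model convergence failures with 3.
"""


class HeatmortError(Exception):
    """Base class for all package errors."""


class ConfigError(HeatmortError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(HeatmortError):
    """Invalid input data; the message lists offending rows/dates."""


class AlignmentError(HeatmortError):
    """Two series that must share a date axis do not."""


class ParseError(HeatmortError):
    """Malformed ICD-10 range expression; names the offending token."""


class RankDeficiencyError(HeatmortError):
    """Design matrix is not full rank; names the collinear columns."""


class ConvergenceError(HeatmortError):
    """IRLS failed to converge and the caller required convergence."""
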