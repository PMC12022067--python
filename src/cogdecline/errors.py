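"""Exception hierarchy.

Contract violations raise specific subclasses so callers (and the CLI) can
distinguish bad configuration from bad data from degenerate statistics.
"""


class CogDeclineError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CogDeclineError, ValueError):
    """Invalid generator/model/feature configuration."""


class SchemaError(CogDeclineError, ValueError):
    """Cohort file violates the data dictionary (names the offending cell)."""


class LabelingError(CogDeclineError, ValueError):
    """Outcome label cannot be computed (e.g. both follow-ups missing)."""


class EstimationError(CogDeclineError, ValueError):
    """A statistic is undefined on the given data (e.g. an empty outcome class)."""


class EvaluationError(CogDeclineError, ValueError):
    """Evaluation impossible (e.g. one outcome class absent from the test set)."""


class ContractError(CogDeclineError, ValueError):
    """Caller broke an API contract (e.g. misaligned feature vector)."""


class IndeterminateEvidenceError(CogDeclineError, ArithmeticError):
    """Zero prior combined with infinite likelihood ratio: 0 x inf evidence."""
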