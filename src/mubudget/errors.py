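"""Exception hierarchy for budget configuration and data problems."""


class BudgetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BudgetError):
    """A budget configuration violates the documented schema.

    The message carries the path to the offending entry, e.g.
    ``quantities.Vt1.standard_uncertainty``.
    """


class InsufficientDataError(BudgetError):
    """Too few observations for the requested statistic."""
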