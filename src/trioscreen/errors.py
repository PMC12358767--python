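"""Exception hierarchy shared across the pipeline stages."""


class TrioscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrioscreenError):
    """Invalid simulation, policy or pipeline configuration."""


class SchemaError(TrioscreenError):
    """An input table is missing required columns or has wrong dtypes."""


class DataError(TrioscreenError):
    """A data value violates its contract (e.g. negative dose)."""


class FitError(TrioscreenError):
    """The conditional likelihood carries no information (no discordant pairs)."""


class RankDeficiencyError(FitError):
    """The information matrix is singular; names the aliased design columns."""

    def __init__(self, aliased_columns):
        self.aliased_columns = list(aliased_columns)
        super().__init__(
            "singular information matrix; aliased design columns: "
            + ", ".join(map(str, self.aliased_columns))
        )


class DegenerateContrastError(TrioscreenError):
    """A Wald contrast with zero standard error."""


class ReportError(TrioscreenError):
    """A report was requested for an incomplete or failed run."""
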