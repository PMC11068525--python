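"""Exception hierarchy for squadflow.

All package-specific failures derive from :class:`SquadflowError` so callers
can catch one type at pipeline boundaries (the CLI maps them to exit codes).
"""


class SquadflowError(Exception):
    """Base class for all squadflow errors."""


class GraphFormatError(SquadflowError):
    """A graph file could not be parsed in the requested format."""


class SignResolutionError(SquadflowError):
    """An edge's regulatory sign could not be determined from the file."""


class TopologyValidationError(SquadflowError):
    """A topology violates structural invariants.

    Carries the full list of issues so a user sees every violation at once.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues)
        super().__init__(f"invalid topology: {lines}")


class LookupError_(SquadflowError):
    """An id (node, channel, parameter) does not exist."""


class DegenerateWeightsError(SquadflowError):
    """A regulator class is present but its weights sum to zero, so the
    combined-input prefactor (1+sum)/sum is undefined."""


class ParameterError(SquadflowError):
    """A parameter set is incomplete or out of its stated domain."""


class IntegrationError(SquadflowError):
    """The ODE solver failed to produce a trajectory."""


class DataError(SquadflowError):
    """Measurement data violate preconditions (e.g. non-positive sigma)."""


class AllDropoutError(DataError):
    """Every cell of a gene/timepoint was a dropout zero."""


class ConfigurationError(SquadflowError):
    """A problem definition is unusable (e.g. no free parameters)."""


class WarmStartError(SquadflowError):
    """Carried-over parameters are incompatible with the new problem."""
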