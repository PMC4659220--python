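"""Exception hierarchy for decision-table validation and rule induction."""


class RoughprogError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RoughprogError):
    """Invalid attribute schema (duplicate names, missing/extra decision...)."""


class UnknownColumnError(RoughprogError):
    """A schema attribute has no matching column in the input file."""


class DomainViolationError(RoughprogError):
    """A cell value is not a member of the attribute's declared domain."""


class MissingCellError(RoughprogError):
    """A cell is empty and the attribute's missing policy is 'reject'."""


class DuplicateObjectError(RoughprogError):
    """Two rows share the same object identifier."""


class NoObjectsError(RoughprogError):
    """The data section of the input is empty."""


class UnknownObjectError(RoughprogError, KeyError):
    """An object identifier is not present in the table."""


class UnknownDecisionValueError(RoughprogError):
    """A decision value is not in the decision attribute's domain."""


class UnorderedDomainError(RoughprogError):
    """An operation requiring a preference order met a plain attribute."""


class UncoveredValueError(RoughprogError):
    """A raw value fell into no bin of the discretization scheme."""


class ConsistencyLevelError(RoughprogError):
    """A consistency level outside the admissible interval (0, 1]."""


class UndefinedRuleConsistencyError(RoughprogError):
    """Rule consistency requested for an antecedent matching no object."""


class ThresholdError(RoughprogError):
    """Decision threshold tau outside [0, 1]."""


class ContradictoryRulesError(RoughprogError):
    """Planted rules assign conflicting decisions to one profile."""
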