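"""Exception hierarchy.

All package-specific failures derive from :class:`PhenoConsensusError` so
callers can catch one base class at pipeline boundaries.
"""


class PhenoConsensusError(Exception):
    """Base class for all package errors."""


class OboParseError(PhenoConsensusError):
    """Malformed OBO input (e.g. a [Term] stanza without an id)."""


class OntologyCycleError(PhenoConsensusError):
    """The is_a relation contains a cycle; carries one offending cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"is_a cycle detected: {' -> '.join(self.cycle)}")


class UnknownTermError(PhenoConsensusError, KeyError):
    """A term identifier that is neither canonical nor an alt_id."""

    def __init__(self, identifier):
        self.identifier = identifier
        super().__init__(f"unresolved term identifier: {identifier!r}")


class AbsentGeneError(PhenoConsensusError, KeyError):
    """A gene identifier absent from the annotated universe."""


class SchemaError(PhenoConsensusError):
    """A tabular input is missing a required column."""


class TableParseError(PhenoConsensusError):
    """A tabular input row could not be parsed; carries the row number."""


class EmptySetError(PhenoConsensusError, ValueError):
    """An operation received an empty collection where >=1 item is required."""


class EmptyCorpusError(PhenoConsensusError):
    """No gene survived corpus construction."""


class DegenerateInputError(PhenoConsensusError, ValueError):
    """A statistic received single-class or otherwise degenerate input."""
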