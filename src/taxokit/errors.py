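"""Exception hierarchy shared across taxokit modules."""


class TaxokitError(Exception):
    """Base class for all taxokit errors."""


class InvalidNameError(TaxokitError):
    """A taxon name is empty or otherwise unusable as a query key."""


class InvalidRankError(TaxokitError):
    """A rank label is unknown to the configured rank order, or a rank
    window is inverted for the lineage at hand."""


class NotFoundError(TaxokitError):
    """A taxid, group or other entity is absent from the store."""


class CorruptTaxonomyError(TaxokitError):
    """The parent-pointer structure contains a cycle or a dangling ancestor."""

    def __init__(self, message: str, taxid: int | None = None):
        super().__init__(message)
        self.taxid = taxid


class EmptySourceError(TaxokitError):
    """A data source was constructed from input with zero parseable records."""


class FixtureSpecError(TaxokitError):
    """A synthetic-taxonomy specification is internally infeasible."""


class ParseError(TaxokitError):
    """A serialized result line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class UsageError(TaxokitError):
    """A command was invoked with an unusable combination of arguments."""
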