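"""Exception hierarchy shared across the package."""


class MycocheckError(Exception):
    """Base class for all package errors."""


class ChecklistSchemaError(MycocheckError):
    """A mandatory column is missing or a row cannot be parsed."""


class RankError(MycocheckError):
    """A name has the wrong taxonomic rank for the requested operation."""


class SynonymResolutionError(MycocheckError):
    """A synonym chain is cyclic or deeper than the configured limit."""


class EmptySelectionError(MycocheckError):
    """A scope filter selected no records."""


class InsufficientSamplesError(MycocheckError):
    """An incidence estimator needs more sampling units than are present."""


class AlignmentError(MycocheckError):
    """Two distance matrices do not share labels/order."""


class ConfigurationError(MycocheckError):
    """A run or simulation configuration is invalid or infeasible."""
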