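"""Exception hierarchy shared across the package."""


class ProteoFRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ProteoFRError):
    """A required column is missing or an input table is malformed."""


class ValidationError(ProteoFRError):
    """A row or value violates a domain invariant."""


class AlignmentError(ProteoFRError):
    """Taxon labels of two objects do not line up."""


class EmptyNetworkError(ProteoFRError):
    """Network construction left no taxon with any weight."""


class InfeasibleError(ProteoFRError):
    """Requested constraints cannot be satisfied (null models, synthesis)."""
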