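"""Exception hierarchy shared across the package."""


class OntosimError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OntosimError):
    """An input file could not be parsed (message names the offending line)."""


class ValidationError(OntosimError):
    """Parsed input violates a structural invariant (cycle, bad counts...)."""


class LookupError_(OntosimError):
    """A concept or report id is not known to the relevant container."""


class ContractError(OntosimError):
    """Two objects passed together are incompatible (space/delta mismatch...)."""


class DegenerateRocError(OntosimError):
    """ROC analysis requested on a single-class label set."""


class UndefinedDenominatorError(OntosimError):
    """Conditional probability requested for a disease with zero corpus count."""
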