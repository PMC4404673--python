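"""Exception hierarchy for pedsem."""


class PedsemError(Exception):
    """Base class for all pedsem errors."""


class PedigreeFormatError(PedsemError):
    """Malformed pedigree/IBD input (missing columns, bad codes, range violations)."""


class PedigreeStructureError(PedsemError):
    """Referential or structural problems: unknown parents, cyclic parentage."""


class ModelSyntaxError(PedsemError):
    """Model-description text could not be parsed."""

    def __init__(self, message, line_no=None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class IdentificationError(PedsemError):
    """Model is under-identified (negative df or rank-deficient moment Jacobian)."""


class ConfigurationError(PedsemError):
    """Inconsistent run configuration (e.g. linkage component without IBD data)."""


class EstimationError(PedsemError):
    """Stage-1 or stage-2 optimization failed."""


class NumericalError(PedsemError):
    """Non-finite values or singular matrices in a numerical routine."""
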