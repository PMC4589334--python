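"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`CsHairpinError`, so callers (and the CLI) can catch one type.
"""


class CsHairpinError(Exception):
    """Base class for all cshairpin errors."""


class FormatError(CsHairpinError):
    """A file does not conform to the expected format."""


class ParseError(FormatError):
    """A cell could not be parsed; carries file/line context in the message."""


class DuplicateRowError(FormatError):
    """Two rows share the same (fragment_id, position)."""


class ContractError(CsHairpinError):
    """A caller violated an interface contract (shape/name/length mismatch)."""


class InsufficientDataError(CsHairpinError):
    """Too little data to compute a quantity (coverage, empty matrix, ...)."""


class EmptyFeatureMatrixError(InsufficientDataError):
    """Every fragment was dropped while building a feature matrix."""


class MissingClassError(CsHairpinError):
    """An operation requires both classes but one is absent or too small."""


class SingularCovarianceError(CsHairpinError):
    """A class covariance is not positive definite."""


class UndefinedRError(CsHairpinError):
    """The error-allowed-scope coefficient R is undefined (eta_corr == 0)."""


class DegenerateInputError(CsHairpinError):
    """Input carries no usable variation (e.g. zero variance everywhere)."""


class InfeasibleFoldsError(CsHairpinError):
    """Requested fold layout cannot be satisfied by the dataset."""
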