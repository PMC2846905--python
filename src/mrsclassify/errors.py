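"""Exception hierarchy.

Every error raised by the library derives from :class:`MrsClassifyError`,
so callers (and the CLI) can catch one type. Names mirror the failure
modes of the pipeline stages: parsing, dataset assembly, feature
selection, model fitting and evaluation.
"""


class MrsClassifyError(Exception):
    """Base class for all mrsclassify errors."""


# --- formats ---------------------------------------------------------------

class UnknownFormat(MrsClassifyError):
    """No input dialect matches the file."""


class ParseError(MrsClassifyError):
    """File content violates its dialect's layout."""


class SchemaError(MrsClassifyError):
    """XML document violates the interchange schema; message carries the
    first offending node path."""


class DuplicateCaseId(MrsClassifyError):
    """Two cases share an identifier within one dataset."""


# --- dataset model ---------------------------------------------------------

class EmptyRoi(MrsClassifyError):
    """Region of interest contains no axis point."""


class ClassOverlap(MrsClassifyError):
    """Two class definitions share a tissue type."""


class NoCases(MrsClassifyError):
    """A design matrix would be empty."""


class EmptyClass(MrsClassifyError):
    """Class profile requested for a class with too few members."""


class MixedAxisLengths(MrsClassifyError):
    """Spectra of different resolutions cannot share one design matrix."""


# --- features --------------------------------------------------------------

class EmptySubset(MrsClassifyError):
    """CFS merit of the empty feature subset is undefined."""


class DegenerateData(MrsClassifyError):
    """All rows identical; no principal directions exist."""


# --- classifier ------------------------------------------------------------

class DimensionMismatch(MrsClassifyError):
    """Input feature count does not match the fitted model."""


class SingularProblem(MrsClassifyError):
    """Between-class scatter vanishes (all class means equal)."""


class NoIntersection(MrsClassifyError):
    """Pairwise boundary lines are parallel (collinear class means)."""


# --- evaluation ------------------------------------------------------------

class TooFewCases(MrsClassifyError):
    """Not enough cases for the requested resampling scheme."""


class UnknownLabel(MrsClassifyError):
    """A label outside the defined classes was encountered."""


class OneClassOnly(MrsClassifyError):
    """ROC needs both positive and negative cases."""


# --- synthetic fixtures ----------------------------------------------------

class OverlappingTypes(MrsClassifyError):
    """Tissue types must be disjoint across synthetic class specs."""


class UnsupportedCombination(MrsClassifyError):
    """Dataset layout cannot be written in the requested dialect."""
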