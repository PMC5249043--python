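"""Exception hierarchy shared across the package."""


class PhysteinerError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PhysteinerError, ValueError):
    """A function argument violates its contract (rates, sizes, thresholds)."""


class FormatError(PhysteinerError, ValueError):
    """A file does not conform to the expected on-disk format."""


class InputError(PhysteinerError, ValueError):
    """Inconsistent inputs (e.g. a class member missing from the feature table)."""


class ConnectivityError(PhysteinerError, RuntimeError):
    """An operation that requires a connected graph received/produced a disconnected one."""


class StructureError(PhysteinerError, ValueError):
    """A graph object violates a structural precondition (not a tree, isolated terminal...)."""


class UndefinedSimilarityError(PhysteinerError, ZeroDivisionError):
    """Jaccard similarity is undefined because both feature vectors are all-zero."""
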