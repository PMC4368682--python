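"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`HelixBundleError` so callers (and the CLI) can catch one type.
"""


class HelixBundleError(Exception):
    """Base class for all package errors."""


class InputError(HelixBundleError):
    """Unreadable, malformed or empty input."""


class EmptyStructureError(InputError):
    """A PDB file (or frame) with zero ATOM records."""


class EnsembleConsistencyError(HelixBundleError):
    """Frames of an ensemble do not share residue topology."""


class SelectionError(HelixBundleError):
    """An atom/residue selection resolved to nothing under strict mode."""


class SequenceError(HelixBundleError):
    """Unknown residue letter or invalid sequence."""


class ParameterError(HelixBundleError):
    """Out-of-range or inconsistent parameter value."""


class AssemblyError(HelixBundleError):
    """Rigid-body assembly could not avoid steric overlap."""


class ClosureError(HelixBundleError):
    """Loop cannot geometrically span its gap."""

    def __init__(self, message: str, min_length: int | None = None):
        super().__init__(message)
        self.min_length = min_length


class GenerationError(HelixBundleError):
    """A synthetic fixture could not satisfy its planted ground truth."""


class DegenerateInputError(HelixBundleError):
    """Too few or collinear points for a superposition."""


class SegmentationError(HelixBundleError):
    """A residue fell outside the structure or segmentation."""


class ComparisonError(HelixBundleError):
    """Incompatible objects compared without an explicit mapping."""


class AssignmentError(HelixBundleError):
    """Secondary-structure assignment impossible (missing backbone atoms)."""
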