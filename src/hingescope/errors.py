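"""Exception hierarchy.

Every error raised by this package derives from :class:`HingescopeError`
so callers can catch the package's failures with a single except clause.
"""


class HingescopeError(Exception):
    """Base class for all hingescope errors."""


class PDBParseError(HingescopeError):
    """A PDB record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(HingescopeError):
    """Input contained no ATOM/HETATM records."""


class EmptySelectionError(HingescopeError):
    """A residue-range selection matched zero atoms."""


class PairingError(HingescopeError):
    """Two point sets that must be paired index-for-index differ in size."""


class UnderDeterminedError(HingescopeError):
    """Too few points to determine a rigid superposition (need >= 3)."""


class ValidationError(HingescopeError):
    """An input violated a numerical invariant (e.g. non-orthonormal rotation)."""


class InsufficientFramesError(HingescopeError):
    """Operation requires more trajectory frames than were supplied."""


class SelectionOverlapError(HingescopeError):
    """Two selections that must be disjoint share atom indices."""


class NoHydrogensError(HingescopeError):
    """Hydrogen-bond detection on a structure without hydrogens.

    Crystal structures usually lack protons; detection would silently
    return nothing. Enable heavy-atom-only mode explicitly to proceed
    with the distance criterion alone.
    """


class ParameterizationError(HingescopeError):
    """Synthetic-generator parameters describe an infeasible geometry."""
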