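"""Exception hierarchy for xylosim.

Every user-facing failure mode has a distinct class so callers (and the CLI)
can report the violated contract by name.
"""


class XylosimError(Exception):
    """Base class for all xylosim errors."""


class GeometryDomainError(XylosimError, ValueError):
    """Geometric inputs outside the valid domain (negative areas, wall
    thicker than the cell, non-positive lumen rectangle)."""


class InvalidParameterError(XylosimError, ValueError):
    """A parameter set violates a model invariant; the message names it."""


class UnknownSpeciesError(XylosimError, KeyError):
    """Requested fixture name is not bundled; the message lists valid names."""


class NonTerminationError(XylosimError, RuntimeError):
    """A simulated cell did not complete lignification within ``tmax``."""


class PhaseUndefinedError(XylosimError, ValueError):
    """Phase durations requested for a trajectory that never reached
    programmed cell death."""


class MissingColumnError(XylosimError, ValueError):
    """A tracheidogram file lacks a mandatory column."""


class NonMonotonePositionError(XylosimError, ValueError):
    """Relative positions in a tracheidogram are not strictly increasing."""


class NegativeTraitError(XylosimError, ValueError):
    """A tracheidogram contains negative trait values."""


class LengthMismatchError(XylosimError, ValueError):
    """Two per-cell series that must be aligned have different lengths."""
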