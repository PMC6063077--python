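"""Cross-sectional geometry of a rectangular conifer tracheid.

A tracheid is modelled as a rectangle of constant tangential diameter
``CTD`` that grows only radially.  Its state is described by three areas:
the whole cross-section ``CA``, the wall ``WA`` and the lignified part of
the wall ``LWA`` (all in um^2).  The wall forms a rectangular annulus of
uniform thickness ``WT`` between the cell outline and the lumen, so

    WA = CA - (CTD - 2*WT) * (CRD - 2*WT),        CRD = CA / CTD

which, solved for ``WT``, gives the smaller root of the quadratic
``4*WT^2 - 2*(CTD + CRD)*WT + WA = 0``.  The larger root corresponds to
walls thicker than the half-cell and is geometrically meaningless.

All functions are pure, accept scalars or numpy arrays, and use um / um^2
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryDomainError, InvalidParameterError

__all__ = [
    "TracheidGeometryConfig",
    "CellSection",
    "DerivedTraits",
    "initial_wall_area",
    "wall_thickness",
    "derived_traits",
]


@dataclass(frozen=True)
class TracheidGeometryConfig:
    """Fixed geometric constants of a species.

    Attributes
    ----------
    CTD : float
        Cell tangential diameter, um; constant during morphogenesis.
    WT0 : float
        Primary (initial) wall thickness, um.
    CA0 : float
        Initial cell cross-section area, um^2.
    WA0 : float
        Initial (primary) wall area, um^2.
    LWA0 : float
        Initial lignified wall area, um^2; always 0.
    """

    CTD: float
    WT0: float
    CA0: float
    WA0: float
    LWA0: float = 0.0

    def __post_init__(self) -> None:
        if self.CTD <= 0:
            raise InvalidParameterError("CTD must be > 0")
        if self.WT0 < 0:
            raise InvalidParameterError("WT0 must be >= 0")
        if not self.CA0 > self.WA0 >= 0:
            raise InvalidParameterError("need CA0 > WA0 >= 0")
        if self.LWA0 != 0.0:
            raise InvalidParameterError("LWA0 must be 0")
        if 2 * self.WT0 >= self.CTD or 2 * self.WT0 >= self.CA0 / self.CTD:
            raise InvalidParameterError(
                "primary wall 2*WT0 must be thinner than both cell diameters"
            )

    @classmethod
    def from_primary_wall(cls, CA0: float, CTD: float, WT0: float) -> "TracheidGeometryConfig":
        """Build a config computing WA0 from the primary-wall annulus."""
        return cls(CTD=CTD, WT0=WT0, CA0=CA0, WA0=initial_wall_area(CA0, CTD, WT0))


@dataclass(frozen=True)
class CellSection:
    """Instantaneous state of one cell: the three areas, um^2."""

    CA: float
    WA: float
    LWA: float

    def __post_init__(self) -> None:
        if not (0 <= self.LWA <= self.WA <= self.CA):
            raise GeometryDomainError(
                f"need 0 <= LWA <= WA <= CA, got ({self.CA}, {self.WA}, {self.LWA})"
            )


@dataclass(frozen=True)
class DerivedTraits:
    """Anatomical traits derived from a cell section.

    WT: wall thickness (um); CRD: cell radial diameter (um);
    LA: lumen area (um^2); LRD: lumen radial diameter (um).
    """

    WT: np.ndarray | float
    CRD: np.ndarray | float
    LA: np.ndarray | float
    LRD: np.ndarray | float


def initial_wall_area(CA0, CTD, WT0):
    """Area of the primary wall annulus for a cell of area ``CA0``.

    ``WA0 = 2*CTD*WT0 + 2*WT0*(CA0/CTD - 2*WT0)``, i.e. two tangential wall
    strips of length CTD plus two radial strips spanning the remaining
    radial extent.  Identical to ``CA0 - (CTD-2*WT0)*(CRD0-2*WT0)``.
    """
    CA0, CTD, WT0 = (np.asarray(v, dtype=float) for v in (CA0, CTD, WT0))
    if np.any(CTD <= 0):
        raise GeometryDomainError("CTD must be > 0")
    if np.any(WT0 < 0):
        raise GeometryDomainError("WT0 must be >= 0")
    if np.any(2 * WT0 >= np.minimum(CTD, CA0 / CTD)) and np.any(WT0 > 0):
        raise GeometryDomainError("lumen rectangle would be non-positive")
    out = 2 * CTD * WT0 + 2 * WT0 * (CA0 / CTD - 2 * WT0)
    return out.item() if out.ndim == 0 else out


def wall_thickness(CA, WA, CTD):
    """Uniform wall thickness of the rectangular annulus, um.

    Smaller root of ``4*WT^2 - 2*(CTD+CRD)*WT + WA = 0`` with
    ``CRD = CA/CTD``:

        WT = (2*(CTD+CRD) - sqrt(4*(CTD+CRD)^2 - 16*WA)) / 8

    The discriminant is analytically >= 0 whenever ``WA <= CA``; tiny
    negative values from floating-point jitter near a closed lumen are
    clamped to zero.
    """
    CA, WA, CTD = (np.asarray(v, dtype=float) for v in (CA, WA, CTD))
    if np.any(CA <= 0) or np.any(WA < 0) or np.any(CTD <= 0):
        raise GeometryDomainError("need CA > 0, WA >= 0, CTD > 0")
    if np.any(WA > CA * (1 + 1e-12)):
        raise GeometryDomainError("wall area cannot exceed cell area")
    p = CTD + CA / CTD
    disc = np.maximum(4.0 * p * p - 16.0 * WA, 0.0)
    out = (2.0 * p - np.sqrt(disc)) / 8.0
    return out.item() if out.ndim == 0 else out


def derived_traits(CA, WA, CTD) -> DerivedTraits:
    """All derived anatomical traits of a section (vectorised)."""
    wt = wall_thickness(CA, WA, CTD)
    CA, WA, CTD = (np.asarray(v, dtype=float) for v in (CA, WA, CTD))
    crd = CA / CTD
    la = CA - WA
    lrd = np.maximum(crd - 2.0 * np.asarray(wt), 0.0)
    if np.ndim(wt) == 0:
        return DerivedTraits(WT=float(wt), CRD=crd.item(), LA=la.item(), LRD=lrd.item())
    return DerivedTraits(WT=wt, CRD=crd, LA=la, LRD=lrd)
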