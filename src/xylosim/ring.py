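"""Season-scale simulation of a whole tree ring.

Sugar availability varies across the ring through a quadratic or
exponential curve S(x) of the relative cell position x in [0, 1] (0 = first
earlywood cell, 1 = last latewood cell), but is constant over each cell's
own development.  Cells grow independently, so a ring is a batch of
single-cell simulations whose terminal anatomies form a simulated
tracheidogram: the ordered per-cell series of lumen area (LA), lumen radial
diameter (LRD) and wall thickness (WT).

Cells are classified as latewood by Mork's criterion in Denne's form: a
cell whose lumen is no wider than twice the double wall (LRD <= 4*WT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .cell import IntegrationConfig, SpeciesParams, integrate_cells, require_completed
from .errors import InvalidParameterError, LengthMismatchError, NegativeTraitError, NonMonotonePositionError
from .geometry import derived_traits

__all__ = [
    "SugarCurve",
    "Tracheidogram",
    "RingResult",
    "mork_classify",
    "latewood_percentage",
    "simulate_ring",
]


@dataclass(frozen=True)
class SugarCurve:
    """Sugar availability as a function of relative ring position.

    quadratic:   S(x) = a*x^2 + b*x + c
    exponential: S(x) = a*exp(b*x) + c

    Coefficients are dimensionless.  The curve must be non-negative on
    [0, 1]; this is checked on a dense grid at construction.
    """

    family: Literal["quadratic", "exponential"]
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.family not in ("quadratic", "exponential"):
            raise InvalidParameterError(f"unknown sugar-curve family {self.family!r}")
        grid = np.linspace(0.0, 1.0, 1001)
        if np.any(self._eval(grid) < 0):
            raise InvalidParameterError("sugar curve must be non-negative on [0, 1]")

    def _eval(self, x):
        if self.family == "quadratic":
            return self.a * x * x + self.b * x + self.c
        return self.a * np.exp(self.b * x) + self.c

    def at(self, x):
        """S at relative position x; domain error outside [0, 1]."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > 1):
            raise InvalidParameterError("relative ring position x must lie in [0, 1]")
        out = self._eval(x)
        return out.item() if out.ndim == 0 else out

    __call__ = at


def mork_classify(LRD, WT):
    """True where a cell is latewood: lumen at most twice the double wall.

    The Mork index 4*WT/LRD >= 1 (ties classified latewood).  A zero wall on
    an open lumen is always earlywood; a fully occluded lumen (LRD = 0) with
    any wall is latewood.
    """
    LRD = np.asarray(LRD, dtype=float)
    WT = np.asarray(WT, dtype=float)
    out = LRD <= 4.0 * WT
    out &= WT > 0
    return out.item() if out.ndim == 0 else out


@dataclass
class Tracheidogram:
    """Ordered per-cell anatomy along one radial file of a tree ring."""

    rel_position: np.ndarray
    LA: np.ndarray
    LRD: np.ndarray
    WT: np.ndarray
    latewood: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rel_position = np.asarray(self.rel_position, dtype=float)
        for name in ("LA", "LRD", "WT"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.rel_position.shape:
                raise LengthMismatchError(f"{name} length {arr.size} != positions {self.rel_position.size}")
            if np.any(arr < 0):
                raise NegativeTraitError(f"trait {name} contains negative values")
            setattr(self, name, arr)
        if self.rel_position.size < 1:
            raise InvalidParameterError("tracheidogram must contain at least one cell")
        if np.any(np.diff(self.rel_position) <= 0):
            raise NonMonotonePositionError("relative positions must be strictly increasing")
        if np.any(self.rel_position < 0) or np.any(self.rel_position > 1):
            raise NonMonotonePositionError("relative positions must lie in [0, 1]")
        if self.latewood is None:
            self.latewood = mork_classify(self.LRD, self.WT)
        else:
            self.latewood = np.asarray(self.latewood, dtype=bool)

    @property
    def n_cells(self) -> int:
        return int(self.rel_position.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, self.n_cells + 1),
                "rel_position": self.rel_position,
                "LA_um2": self.LA,
                "LRD_um": self.LRD,
                "WT_um": self.WT,
                "latewood": self.latewood.astype(int),
            }
        )


def latewood_percentage(tr: Tracheidogram) -> float:
    """Percent of cells flagged latewood (Mork/Denne)."""
    if tr.n_cells == 0:
        raise InvalidParameterError("empty tracheidogram")
    return 100.0 * float(np.count_nonzero(tr.latewood)) / tr.n_cells


@dataclass
class RingResult:
    """A simulated ring: tracheidogram plus per-cell kinetic summaries."""

    tracheidogram: Tracheidogram
    enlargement_days: np.ndarray
    thickening_days: np.ndarray
    S: np.ndarray
    completed: np.ndarray


def simulate_ring(
    p: SpeciesParams,
    curve: SugarCurve,
    n_cells: int = 100,
    cfg: IntegrationConfig | None = None,
    on_incomplete: Literal["raise", "keep"] = "raise",
) -> RingResult:
    """Simulate ``n_cells`` independent cells at positions x_i = (i-1)/(n-1).

    Each cell's terminal anatomy enters the tracheidogram; enlargement and
    thickening durations are the interpolated event times of its own
    simulation.  A cell that fails to complete lignification by ``tmax``
    raises ``NonTerminationError`` naming its index, unless
    ``on_incomplete='keep'``, in which case its durations are NaN and its
    terminal (still unlignified) anatomy is reported.
    """
    if n_cells < 2:
        raise InvalidParameterError("need at least 2 cells to span the ring")
    cfg = cfg or IntegrationConfig()
    x = np.linspace(0.0, 1.0, n_cells)
    S = np.asarray(curve.at(x), dtype=float)
    res = integrate_cells(p, S, cfg, record=False)
    if on_incomplete == "raise":
        require_completed(res, what=f"{p.name} ring cell")
    traits = derived_traits(res["CA"], res["WA"], np.full(n_cells, p.geometry.CTD))
    tr = Tracheidogram(
        rel_position=x,
        LA=traits.LA,
        LRD=traits.LRD,
        WT=traits.WT,
        metadata={
            "species": p.name,
            "n_cells": n_cells,
            "source": "simulated",
            "curve_family": curve.family,
            "a": curve.a,
            "b": curve.b,
            "c": curve.c,
        },
    )
    thick = res["t_death"] - res["t_enl_end"]
    return RingResult(
        tracheidogram=tr,
        enlargement_days=res["t_enl_end"],
        thickening_days=thick,
        S=S,
        completed=res["completed"],
    )
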