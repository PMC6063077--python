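"""Kinetics of a single differentiating tracheid.

The cell is a coupled three-variable ODE system in (CA, WA, LWA):

    dCA/dt  = vc * CA * (1 - CA/CAmax) * (1 - min(1, WT/WT*))
    dWA/dt  = vw * S * (1 - WA/WAmax) * f(LA/mw; sw)  * Death
    dLWA/dt = vl * S *                 f(LA/ml; sl)   * Death

with LA = CA - WA the lumen area, WT the wall thickness recomputed from
(CA, WA) at every evaluation, and Death the boolean that freezes wall
dynamics once the wall is completely lignified (LWA >= WA).  Enlargement is
logistic toward CAmax, braked linearly by wall thickness and stopped
irreversibly once WT reaches the threshold WT*.  Wall deposition and
lignification are driven by the sugar availability S (dimensionless,
constant over one cell's development) and saturate with the lumen area
through the sigmoid

    f(u; s) = u^s / (1 + u^s)

so both processes shut down as the lumen closes, and deposition is also
capped by the maximum wall area WAmax.

Integration is classical fixed-step Runge-Kutta 4.  The two events of
interest -- the end of enlargement (first WT >= WT* crossing) and
programmed cell death (LWA catches WA within ``death_tol``) -- are located
by linear interpolation between the bracketing steps, which removes the
O(dt) bias a step-quantised event time would carry.  At death LWA is
clamped to WA and all derivatives are frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NonTerminationError, PhaseUndefinedError
from .geometry import CellSection, DerivedTraits, TracheidGeometryConfig, derived_traits, wall_thickness

__all__ = [
    "KineticParams",
    "SpeciesParams",
    "IntegrationConfig",
    "CellTrajectory",
    "enlargement_rate",
    "wall_deposition_rate",
    "lignification_rate",
    "simulate_cell",
    "phase_durations",
]

#: Enlargement is also declared over if the area growth rate falls below
#: this floor (um^2/d); guards parameter sets whose WT never reaches WT*.
STALL_RATE = 1e-6


@dataclass(frozen=True)
class KineticParams:
    """Calibrated per-species rate constants.

    vc : specific enlargement rate, 1/d
    CAmax : maximum cell area, um^2
    WTstar : wall-thickness threshold ending enlargement, um
    vw : maximum wall-deposition rate, um^2/d
    WAmax : maximum wall area, um^2
    mw, sw : lumen-area scale (um^2) and exponent of the deposition sigmoid
    vl : maximum lignification rate, um^2/d
    ml, sl : lumen-area scale (um^2) and exponent of the lignification sigmoid
    """

    vc: float
    CAmax: float
    WTstar: float
    vw: float
    WAmax: float
    mw: float
    sw: float
    vl: float
    ml: float
    sl: float

    def __post_init__(self) -> None:
        for name in ("vc", "CAmax", "WTstar", "vw", "WAmax", "mw", "sw", "vl", "ml", "sl"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"kinetic parameter {name} must be > 0")


@dataclass(frozen=True)
class SpeciesParams:
    """Complete parameter set for one species."""

    name: str
    geometry: TracheidGeometryConfig
    kinetics: KineticParams

    def __post_init__(self) -> None:
        g, k = self.geometry, self.kinetics
        if k.WTstar <= g.WT0:
            raise InvalidParameterError(f"WTstar must exceed WT0 ({k.WTstar} <= {g.WT0})")
        if k.WAmax <= g.WA0:
            raise InvalidParameterError(f"WAmax must exceed WA0 ({k.WAmax} <= {g.WA0})")
        if k.CAmax <= g.CA0:
            raise InvalidParameterError(f"CAmax must exceed CA0 ({k.CAmax} <= {g.CA0})")

    def replace_kinetics(self, **kwargs) -> "SpeciesParams":
        return replace(self, kinetics=replace(self.kinetics, **kwargs))


@dataclass(frozen=True)
class IntegrationConfig:
    """Fixed-step RK4 settings.

    dt : time step, d.  The default 0.01 d makes RK4 error negligible for
        rates of O(10 um^2/d) on states of O(10^2-10^3 um^2); halving it
        moves event times and final states by well under 0.1 %.
    tmax : bail-out horizon, d.
    death_tol : wall is considered fully lignified when WA - LWA <= this, um^2.
    """

    dt: float = 0.01
    tmax: float = 200.0
    death_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tmax <= 0:
            raise InvalidParameterError("dt and tmax must be > 0")
        if self.death_tol < 0:
            raise InvalidParameterError("death_tol must be >= 0")


def _saturation(lumen, m, s):
    """Sigmoid f(u) = u^s / (1 + u^s) with u = lumen/m; 0 at a closed lumen."""
    u = np.maximum(lumen, 0.0) / m
    us = u ** s
    return us / (1.0 + us)


def enlargement_rate(state: CellSection, S, p: SpeciesParams):
    """dCA/dt, um^2/d.  Independent of sugar; stops at CA=CAmax or WT>=WT*."""
    k = p.kinetics
    wt = wall_thickness(state.CA, state.WA, p.geometry.CTD)
    return k.vc * state.CA * (1.0 - state.CA / k.CAmax) * (1.0 - min(1.0, wt / k.WTstar))


def wall_deposition_rate(state: CellSection, S, p: SpeciesParams):
    """dWA/dt, um^2/d; zero after death (LWA >= WA)."""
    if state.LWA >= state.WA:
        return 0.0
    k = p.kinetics
    lumen = state.CA - state.WA
    return k.vw * S * (1.0 - state.WA / k.WAmax) * float(_saturation(lumen, k.mw, k.sw))


def lignification_rate(state: CellSection, S, p: SpeciesParams):
    """dLWA/dt, um^2/d; zero after death (LWA >= WA)."""
    if state.LWA >= state.WA:
        return 0.0
    k = p.kinetics
    lumen = state.CA - state.WA
    return k.vl * S * float(_saturation(lumen, k.ml, k.sl))


@dataclass
class CellTrajectory:
    """Full time course of one simulated cell.

    ``t_enl_end`` is the first time the enlargement brake closes (WT
    crossing WT*, a stalled area rate, or death, whichever comes first);
    ``t_death`` the interpolated completion of lignification (NaN if the
    cell never died before ``tmax``, in which case ``completed`` is False).
    """

    times: np.ndarray
    CA: np.ndarray
    WA: np.ndarray
    LWA: np.ndarray
    S: float
    species: str
    t_enl_end: float
    t_death: float
    completed: bool
    CTD: float
    config: IntegrationConfig = field(default_factory=IntegrationConfig)

    @property
    def traits(self) -> DerivedTraits:
        return derived_traits(self.CA, self.WA, self.CTD)

    @property
    def final_state(self) -> CellSection:
        return CellSection(float(self.CA[-1]), float(self.WA[-1]), float(min(self.LWA[-1], self.WA[-1])))

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        phase = np.where(t < self.t_enl_end, "enlarging", "thickening")
        if self.completed:
            phase = np.where(t >= self.t_death, "dead", phase)
        return phase

    def to_frame(self) -> pd.DataFrame:
        tr = self.traits
        return pd.DataFrame(
            {
                "time_d": self.times,
                "CA_um2": self.CA,
                "WA_um2": self.WA,
                "LWA_um2": self.LWA,
                "WT_um": tr.WT,
                "LA_um2": tr.LA,
                "LRD_um": tr.LRD,
                "phase": self.phase_at(self.times),
            }
        )


def _rhs(CA, WA, LWA, S, k, CTD):
    """Vectorised right-hand side; WT recomputed at every stage evaluation."""
    p = CTD + CA / CTD
    wt = (2.0 * p - np.sqrt(np.maximum(4.0 * p * p - 16.0 * WA, 0.0))) / 8.0
    dCA = k.vc * CA * (1.0 - CA / k.CAmax) * (1.0 - np.minimum(1.0, wt / k.WTstar))
    lumen = np.maximum(CA - WA, 0.0)
    death = (LWA < WA).astype(float)
    dWA = k.vw * S * (1.0 - WA / k.WAmax) * _saturation(lumen, k.mw, k.sw) * death
    dLWA = k.vl * S * _saturation(lumen, k.ml, k.sl) * death
    return dCA, dWA, dLWA


def integrate_cells(p: SpeciesParams, S, cfg: IntegrationConfig, record: bool = False):
    """RK4-integrate a batch of independent cells sharing one parameter set.

    Parameters
    ----------
    S : array-like
        Sugar availability per cell; each cell sees a constant S.
    record : bool
        If True, keep the full state history (times x cells x 3).

    Returns
    -------
    dict with final ``CA``/``WA``/``LWA`` arrays, interpolated ``t_enl_end``
    and ``t_death`` (NaN when the event never occurred), ``completed``
    boolean mask, and, when recording, ``times`` and ``states``.
    """
    k, g = p.kinetics, p.geometry
    S = np.atleast_1d(np.asarray(S, dtype=float))
    if np.any(S < 0):
        raise InvalidParameterError("sugar availability S must be >= 0")
    n = S.shape[0]
    CA = np.full(n, g.CA0, dtype=float)
    WA = np.full(n, g.WA0, dtype=float)
    LWA = np.full(n, g.LWA0, dtype=float)
    alive = np.ones(n, dtype=bool)
    t_enl = np.full(n, np.nan)
    t_death = np.full(n, np.nan)
    dt, ctd = cfg.dt, g.CTD
    wt_prev = wall_thickness(CA, WA, np.full(n, ctd))
    if np.ndim(wt_prev) == 0:
        wt_prev = np.atleast_1d(wt_prev)
    # threshold may already be met (degenerate but allowed via replace_kinetics)
    t_enl[wt_prev >= k.WTstar] = 0.0

    history = [(0.0, CA.copy(), WA.copy(), LWA.copy())] if record else None
    t = 0.0
    n_steps = int(np.ceil(cfg.tmax / dt))
    for _ in range(n_steps):
        if not alive.any():
            break
        k1 = _rhs(CA, WA, LWA, S, k, ctd)
        k2 = _rhs(CA + 0.5 * dt * k1[0], WA + 0.5 * dt * k1[1], LWA + 0.5 * dt * k1[2], S, k, ctd)
        k3 = _rhs(CA + 0.5 * dt * k2[0], WA + 0.5 * dt * k2[1], LWA + 0.5 * dt * k2[2], S, k, ctd)
        k4 = _rhs(CA + dt * k3[0], WA + dt * k3[1], LWA + dt * k3[2], S, k, ctd)
        dCA = dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        dWA = dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        dLWA = dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        gap0 = WA - LWA
        CA_prev, WA_prev, LWA_prev = CA, WA, LWA
        CA = np.where(alive, CA + dCA, CA)
        WA = np.where(alive, WA + dWA, WA)
        LWA = np.where(alive, LWA + dLWA, LWA)
        t += dt

        wt = np.atleast_1d(wall_thickness(CA, WA, np.full(n, ctd)))
        need_enl = alive & np.isnan(t_enl)
        crossing = need_enl & (wt >= k.WTstar)
        if crossing.any():
            frac = np.where(wt > wt_prev, (k.WTstar - wt_prev) / np.where(wt > wt_prev, wt - wt_prev, 1.0), 1.0)
            t_enl = np.where(crossing, t - dt + dt * np.clip(frac, 0.0, 1.0), t_enl)
        stalled = need_enl & ~crossing & (dCA / dt < STALL_RATE)
        t_enl = np.where(stalled, t, t_enl)

        gap1 = WA - LWA
        dying = alive & (gap1 <= cfg.death_tol)
        if dying.any():
            closing = gap0 - gap1
            frac = np.clip(
                np.where(closing > 0, gap0 / np.where(closing > 0, closing, 1.0), 1.0), 0.0, 1.0
            )
            t_death = np.where(dying, t - dt + dt * frac, t_death)
            # freeze the cell at its state at the interpolated crossing, so
            # terminal anatomy varies smoothly with dt and with parameters
            CA = np.where(dying, CA_prev + frac * dCA, CA)
            WA = np.where(dying, WA_prev + frac * dWA, WA)
            LWA = np.where(dying, WA, LWA)
            alive &= ~dying
        wt_prev = wt
        if record:
            history.append((t, CA.copy(), WA.copy(), LWA.copy()))

    # death also ends enlargement for cells that never reached WT*
    t_enl = np.where(np.isnan(t_enl) & ~np.isnan(t_death), t_death, t_enl)
    out = {
        "CA": CA,
        "WA": WA,
        "LWA": np.minimum(LWA, WA),
        "t_enl_end": t_enl,
        "t_death": t_death,
        "completed": ~alive,
        "S": S,
    }
    if record:
        out["times"] = np.array([h[0] for h in history])
        out["states"] = np.stack([np.stack(h[1:], axis=-1) for h in history])  # (steps, n, 3)
    return out


def simulate_cell(p: SpeciesParams, S: float, cfg: IntegrationConfig | None = None) -> CellTrajectory:
    """Simulate one cell at constant sugar availability ``S``.

    The trajectory is sampled at every RK4 step.  If lignification does not
    complete by ``cfg.tmax`` (e.g. S = 0 leaves the wall untouched) the
    trajectory is returned with ``completed=False`` and ``t_death=NaN``.
    """
    cfg = cfg or IntegrationConfig()
    res = integrate_cells(p, [float(S)], cfg, record=True)
    return CellTrajectory(
        times=res["times"],
        CA=res["states"][:, 0, 0],
        WA=res["states"][:, 0, 1],
        LWA=np.minimum(res["states"][:, 0, 2], res["states"][:, 0, 1]),
        S=float(S),
        species=p.name,
        t_enl_end=float(res["t_enl_end"][0]),
        t_death=float(res["t_death"][0]),
        completed=bool(res["completed"][0]),
        CTD=p.geometry.CTD,
        config=cfg,
    )


def phase_durations(traj: CellTrajectory) -> tuple[float, float]:
    """(enlargement, thickening) durations in days.

    Enlargement runs from division (t = 0) to ``t_enl_end``; thickening from
    there to programmed cell death.  Raises if the cell never died.
    """
    if not traj.completed or np.isnan(traj.t_death):
        raise PhaseUndefinedError(
            f"cell (S={traj.S}) did not complete lignification by tmax; phase durations undefined"
        )
    enl = traj.t_enl_end
    return float(enl), float(traj.t_death - enl)


def require_completed(res: dict, what: str = "cell") -> None:
    """Raise NonTerminationError naming the first offending cell index."""
    bad = np.nonzero(~res["completed"])[0]
    if bad.size:
        i = int(bad[0])
        raise NonTerminationError(
            f"{what} {i} (S={res['S'][i]:.4g}) did not complete lignification by tmax "
            f"({bad.size} incomplete in total); raise tmax or inspect parameters"
        )
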