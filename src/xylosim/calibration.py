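"""Least-squares calibration of model parameters to a tracheidogram.

The objective is the unweighted sum of squared errors over the three
per-cell traits,

    SSE = sum_i (WT_i - WT*_i)^2 + sum_i (LRD_i - LRD*_i)^2
        + sum_i (LA_i - LA*_i)^2

with starred values predicted by the forward ring simulation.  The three
terms are summed in raw units (um and um^2), so the lumen-area term
numerically dominates; an optional per-trait weighting hook exists but is
off by default.  Minimisation uses the Nelder-Mead simplex
(scipy.optimize), run in log-space for positivity-constrained parameters
(all kinetic constants and the curve offset c; the curve coefficients a and
b may legitimately be negative and are fitted untransformed), with a small
number of multi-starts from deterministically jittered initial points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .cell import IntegrationConfig, SpeciesParams
from .errors import InvalidParameterError, LengthMismatchError, XylosimError
from .ring import SugarCurve, Tracheidogram, simulate_ring

__all__ = [
    "FREE_PARAMETER_NAMES",
    "CalibrationSpec",
    "CalibrationResult",
    "standardize_tracheidogram",
    "sse_objective",
    "calibrate",
    "fit_statistics",
]

KINETIC_NAMES = ("vc", "CAmax", "WTstar", "vw", "WAmax", "mw", "sw", "vl", "ml", "sl")
CURVE_NAMES = ("a", "b", "c")
FREE_PARAMETER_NAMES = KINETIC_NAMES + CURVE_NAMES
#: parameters constrained positive and therefore fitted in log-space
_LOG_SPACE = set(KINETIC_NAMES) | {"c"}

_PENALTY = 1e30


@dataclass
class CalibrationSpec:
    """What to fit and how.

    free : names of the free parameters (kinetics and/or curve coefficients).
    initial : starting values keyed by name; defaults are taken from the
        base species / curve where omitted.
    curve_family : family of the sugar curve used by the forward model.
    n_cells : cells of the forward ring; the observed tracheidogram must
        already be standardized to this count.
    maxiter, xatol, fatol : Nelder-Mead settings.
    restarts : number of additional starts from jittered initials.
    jitter : relative half-width of the multi-start perturbation.
    seed : seed of the (deterministic) jitter generator.
    weights : optional (w_wt, w_lrd, w_la); 1 each by default.
    """

    free: Sequence[str]
    curve_family: str = "quadratic"
    initial: dict = field(default_factory=dict)
    n_cells: int = 50
    integration: IntegrationConfig = field(default_factory=lambda: IntegrationConfig(dt=0.1))
    maxiter: int = 3000
    xatol: float = 1e-8
    fatol: float = 1e-9
    restarts: int = 4
    jitter: float = 0.10
    seed: int = 42
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.free:
            raise InvalidParameterError("the free-parameter set must be non-empty")
        unknown = [n for n in self.free if n not in FREE_PARAMETER_NAMES]
        if unknown:
            raise InvalidParameterError(
                f"unknown free parameter(s) {unknown}; valid: {FREE_PARAMETER_NAMES}"
            )


@dataclass
class CalibrationResult:
    """Outcome of a calibration run."""

    params: dict
    sse: float
    components: dict
    r2: dict
    converged: bool
    n_iter: int
    n_fev: int
    start_sse: float


def standardize_tracheidogram(tr: Tracheidogram, n_target: int) -> Tracheidogram:
    """Resample a tracheidogram onto ``n_target`` evenly spaced cells.

    Linear interpolation of each trait on normalized position; both
    endpoints are preserved exactly.  This is the usual step that brings
    rings with different cell counts onto a species' mean cell count.
    """
    if tr.n_cells < 2:
        raise LengthMismatchError("need at least 2 cells to standardize")
    if n_target < 2:
        raise LengthMismatchError("target cell count must be >= 2")
    x_new = np.linspace(0.0, 1.0, n_target)
    # map source positions onto [0, 1] regardless of their original span
    x_old = tr.rel_position
    x_old = (x_old - x_old[0]) / (x_old[-1] - x_old[0])
    meta = dict(tr.metadata)
    meta["n_cells"] = n_target
    return Tracheidogram(
        rel_position=x_new,
        LA=np.interp(x_new, x_old, tr.LA),
        LRD=np.interp(x_new, x_old, tr.LRD),
        WT=np.interp(x_new, x_old, tr.WT),
        metadata=meta,
    )


def _apply_free(values, spec: CalibrationSpec, base: SpeciesParams, base_curve: SugarCurve):
    """Substitute free values into the base parameter set; may raise."""
    named = dict(zip(spec.free, values))
    kin_updates = {k: v for k, v in named.items() if k in KINETIC_NAMES}
    p = replace(base, kinetics=replace(base.kinetics, **kin_updates)) if kin_updates else base
    curve_coefs = {k: getattr(base_curve, k) for k in CURVE_NAMES}
    curve_coefs.update({k: v for k, v in named.items() if k in CURVE_NAMES})
    curve = SugarCurve(family=spec.curve_family, **curve_coefs)
    return p, curve


def sse_objective(
    free_values,
    spec: CalibrationSpec,
    observed: Tracheidogram,
    base: SpeciesParams,
    base_curve: SugarCurve,
) -> float:
    """SSE of the forward model at the given free-parameter values.

    Invalid parameter sets and rings with non-terminating cells return a
    large penalty instead of raising, so the simplex can step over them.
    """
    if observed.n_cells != spec.n_cells:
        raise LengthMismatchError(
            f"observed tracheidogram has {observed.n_cells} cells but the forward model "
            f"uses {spec.n_cells}; standardize_tracheidogram() first"
        )
    try:
        p, curve = _apply_free(np.asarray(free_values, dtype=float), spec, base, base_curve)
        ring = simulate_ring(p, curve, n_cells=spec.n_cells, cfg=spec.integration)
    except XylosimError:
        return _PENALTY
    sim = ring.tracheidogram
    w_wt, w_lrd, w_la = spec.weights
    return float(
        w_wt * np.sum((observed.WT - sim.WT) ** 2)
        + w_lrd * np.sum((observed.LRD - sim.LRD) ** 2)
        + w_la * np.sum((observed.LA - sim.LA) ** 2)
    )


def _sse_components(observed: Tracheidogram, sim: Tracheidogram) -> dict:
    return {
        "WT": float(np.sum((observed.WT - sim.WT) ** 2)),
        "LRD": float(np.sum((observed.LRD - sim.LRD) ** 2)),
        "LA": float(np.sum((observed.LA - sim.LA) ** 2)),
    }


def fit_statistics(observed: Tracheidogram, simulated: Tracheidogram) -> dict:
    """Per-trait SSE and coefficient of determination R^2.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the observed mean; a
    constant predictor scores 0, a perfect one 1.
    """
    if observed.n_cells != simulated.n_cells:
        raise LengthMismatchError(
            f"length mismatch: observed {observed.n_cells} vs simulated {simulated.n_cells}"
        )
    out = {}
    for name in ("WT", "LRD", "LA"):
        o = getattr(observed, name)
        s = getattr(simulated, name)
        ss_res = float(np.sum((o - s) ** 2))
        ss_tot = float(np.sum((o - o.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
        out[name] = {"sse": ss_res, "r2": r2}
    return out


def _encode(values, names):
    return np.array([np.log(v) if n in _LOG_SPACE else v for v, n in zip(values, names)])


def _decode(z, names):
    return np.array([np.exp(v) if n in _LOG_SPACE else v for v, n in zip(z, names)])


def calibrate(
    observed: Tracheidogram,
    spec: CalibrationSpec,
    base: SpeciesParams,
    base_curve: SugarCurve,
) -> CalibrationResult:
    """Nelder-Mead minimisation of the SSE over the free parameters.

    Deterministic for a fixed spec: multi-start jitter uses ``spec.seed``.
    Non-convergence of the simplex is reported through ``converged``; the
    best point found is always returned.
    """
    names = list(spec.free)
    x0 = np.array(
        [
            float(
                spec.initial.get(
                    n,
                    getattr(base.kinetics, n) if n in KINETIC_NAMES else getattr(base_curve, n),
                )
            )
            for n in names
        ]
    )
    for n, v in zip(names, x0):
        if n in _LOG_SPACE and v <= 0:
            raise InvalidParameterError(f"initial value of {n} must be > 0 (got {v})")

    def fun(z):
        return sse_objective(_decode(z, names), spec, observed, base, base_curve)

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    for _ in range(spec.restarts):
        starts.append(x0 * (1.0 + spec.jitter * (2.0 * rng.random(len(names)) - 1.0)))
    start_sse = fun(_encode(x0, names))
    best = None
    for s in starts:
        res = minimize(
            fun,
            _encode(s, names),
            method="Nelder-Mead",
            options={
                "maxiter": spec.maxiter,
                "xatol": spec.xatol,
                "fatol": spec.fatol,
                "adaptive": True,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    fitted = dict(zip(names, _decode(best.x, names)))
    p, curve = _apply_free(_decode(best.x, names), spec, base, base_curve)
    sim = simulate_ring(p, curve, n_cells=spec.n_cells, cfg=spec.integration).tracheidogram
    return CalibrationResult(
        params={k: float(v) for k, v in fitted.items()},
        sse=float(best.fun),
        components=_sse_components(observed, sim),
        r2={k: v["r2"] for k, v in fit_statistics(observed, sim).items()},
        converged=bool(best.success),
        n_iter=int(best.nit),
        n_fev=int(best.nfev),
        start_sse=float(start_sse),
    )
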