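"""Observed-like tracheidograms with known ground truth.

Real mean tracheidograms are averages of measured radial files; their
measurement error is not characterised.  For testing the calibration
machinery this module perturbs a simulated ring with independent
multiplicative Gaussian noise per trait and cell:

    trait_noisy = trait * (1 + CV * z),   z ~ N(0, 1), factor truncated > 0

Multiplicative (CV-based) noise keeps the three traits — which span two
orders of magnitude (WT ~ 3 um, LA ~ 10^3 um^2) — comparably perturbed and
strictly positive.  The generating parameters, curve and seed are stored in
the tracheidogram metadata, so recovery experiments know their truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import IntegrationConfig, SpeciesParams
from .errors import InvalidParameterError
from .ring import SugarCurve, Tracheidogram, mork_classify, simulate_ring

__all__ = ["NoiseModel", "generate_synthetic_observations"]


@dataclass(frozen=True)
class NoiseModel:
    """Per-trait coefficients of variation and the RNG seed."""

    cv_wt: float = 0.02
    cv_lrd: float = 0.02
    cv_la: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv_wt, self.cv_lrd, self.cv_la) < 0:
            raise InvalidParameterError("coefficients of variation must be >= 0")


def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values.copy()
    factor = 1.0 + cv * rng.standard_normal(values.shape)
    # truncate at zero: redraw the (practically nonexistent at cv <= 0.1) negatives
    bad = factor <= 0
    while np.any(bad):
        factor[bad] = 1.0 + cv * rng.standard_normal(int(bad.sum()))
        bad = factor <= 0
    return values * factor


def generate_synthetic_observations(
    p: SpeciesParams,
    curve: SugarCurve,
    n_cells: int,
    noise: NoiseModel | None = None,
    cfg: IntegrationConfig | None = None,
) -> Tracheidogram:
    """Simulate a ring and overlay trait noise; bit-reproducible per seed.

    The latewood flags are recomputed from the noisy LRD and WT.  Ground
    truth (parameters, curve, seed) is kept in ``metadata['truth']``.
    """
    noise = noise or NoiseModel()
    ring = simulate_ring(p, curve, n_cells=n_cells, cfg=cfg)
    tr = ring.tracheidogram
    rng = np.random.default_rng(noise.seed)
    wt = _noisy(tr.WT, noise.cv_wt, rng)
    lrd = _noisy(tr.LRD, noise.cv_lrd, rng)
    la = _noisy(tr.LA, noise.cv_la, rng)
    meta = dict(tr.metadata)
    meta.update(
        source="synthetic",
        noise={"cv_wt": noise.cv_wt, "cv_lrd": noise.cv_lrd, "cv_la": noise.cv_la, "seed": noise.seed},
        truth={
            "kinetics": {k: getattr(p.kinetics, k) for k in ("vc", "CAmax", "WTstar", "vw", "WAmax", "mw", "sw", "vl", "ml", "sl")},
            "curve": {"family": curve.family, "a": curve.a, "b": curve.b, "c": curve.c},
        },
    )
    return Tracheidogram(
        rel_position=tr.rel_position.copy(),
        LA=la,
        LRD=lrd,
        WT=wt,
        latewood=mork_classify(lrd, wt),
        metadata=meta,
    )
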