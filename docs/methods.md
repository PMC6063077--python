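# Methods

## Model

A conifer tracheid is represented in transverse section as a rectangle of
fixed tangential diameter `CTD` (μm) that enlarges only radially.  Three
state variables, all in μm², describe it: total cross-section area `CA`,
wall area `WA`, and lignified wall area `LWA`.  The wall is a rectangular
annulus of uniform thickness, so the wall thickness `WT` is the smaller
root of `4·WT² − 2·(CTD + CRD)·WT + WA = 0` with `CRD = CA/CTD`; the larger
root would imply walls thicker than the half-cell.  Derived anatomy:
lumen area `LA = CA − WA`, lumen radial diameter `LRD = CRD − 2·WT`.

The dynamics couple three processes:

* **Enlargement** — logistic growth of `CA` toward `CAmax` at specific rate
  `vc` (1/d), braked linearly by relative wall thickness and stopped
  irreversibly once `WT` reaches the threshold `WT*`.  Mechanistically, each
  deposited wall layer stiffens the sacculus and reduces wall relaxation;
  the threshold is where relaxation ceases entirely.
* **Wall deposition** — `dWA/dt = vw·S·(1 − WA/WAmax)·f(LA/mw; sw)·Death`,
  with `S` the dimensionless sugar availability.
* **Lignification** — `dLWA/dt = vl·S·f(LA/ml; sl)·Death`.

`f(u; s) = u^s/(1+u^s)` is a saturating sigmoid of the lumen area with
half-saturation scale `m` (μm²) and steepness `s`: wall-building material is
delivered across the lumen–wall contact surface, so both processes slow and
finally stop as the lumen closes.  `Death` is the boolean `LWA < WA`; when
lignification catches up with deposition the cell undergoes programmed
death and all dynamics freeze.

The sign structure produces the earlywood–latewood contrast without any
phase calendar: at low `S`, deposition is slow, `WT*` is reached late, and
the cell ends large and thin-walled; at high `S`, the wall races ahead,
enlargement stops early, and the small cell accumulates a thick wall.

Within a ring, cell `i` of `n` develops at constant
`S(x_i)`, `x_i = (i−1)/(n−1)`, where `S(x)` is either quadratic
(`a·x² + b·x + c`) or exponential (`a·e^{b·x} + c`) and must be
non-negative on [0, 1] (checked on a dense grid at construction).  Cells are
mutually independent, so ring simulation is a vectorised batch of
single-cell integrations.  Latewood is flagged per cell by Mork's criterion
in Denne's form, `LRD ≤ 4·WT` (ties latewood; a cell with `WT = 0` is never
latewood).

### On the form of the saturation term

The saturation bracket is implemented as `1 − 1/(1 + (LA/m)^s)`, i.e. a
Hill-type sigmoid in the lumen area.  With the bundled parameter tables this
form reproduces the published behaviour of all four species far better than
the alternative `1 − (1 + LA/m)^(−s)` reading (which, for the two species
whose `m` exceeds the initial lumen area, floods the young cell with wall
material and drives the entire ring to latewood, and which leaves
late-season cells in a non-terminating occluded state).  It is also the
natural mechanistic choice: deposition is negligible while the lumen is
small relative to `m` and approaches its maximal rate once the lumen is
well developed.

## Parameters

Fixed per species (measured): `CA0`, `WA0`, `LWA0 = 0`, `CTD`, `WT0`.  The
primary-wall area is consistent with the annulus formula
`WA0 = 2·CTD·WT0 + 2·WT0·(CA0/CTD − 2·WT0)`; the bundled values reproduce
it within rounding (±0.5 μm²).  Calibrated per species: `vc`, `CAmax`,
`WT*`, `vw`, `WAmax`, `mw`, `sw`, `vl`, `ml`, `sl` and the curve
coefficients `a`, `b`, `c`.  Four fixtures ship with the package
(*Pinus cembra*, *Picea abies*, *Larix decidua*, *Picea mariana*); `mw` and
`ml` are treated as lumen-area scales (μm²), the units that make the
saturation argument dimensionless.

## Numerics

* Classical RK4 with fixed step, default `dt = 0.01` d and `tmax = 200` d.
  Rates are O(10 μm²/d) on states of O(10²–10³ μm²); halving `dt` moves
  event times and final states by under 0.02 % for all fixtures (asserted
  at <0.1 % in the suite).
* `WT` is recomputed from `(CA, WA)` at every RK4 stage evaluation; the
  discriminant of the annulus quadratic is clamped at 0 against
  floating-point jitter near a closed lumen.
* Both events are located by linear interpolation between bracketing steps:
  the enlargement end (first `WT ≥ WT*` crossing) and death (`WA − LWA`
  falling below `death_tol`, default 10⁻⁶ μm²).  The dying cell's state is
  also interpolated to the crossing, which makes terminal anatomy smooth in
  both `dt` and parameters — without this the calibration objective has
  step discontinuities that stall the simplex.
* Death ends enlargement trivially for cells that die before reaching
  `WT*` (slow-wall, low-S regime); a stalled area rate (< 10⁻⁶ μm²/d)
  also closes the phase, guarding parameter sets whose threshold is never
  reached.  A cell that has not died by `tmax` is reported as incomplete:
  `simulate_cell` flags it, `phase_durations` raises, and `simulate_ring`
  raises with the cell index (or returns NaN durations with
  `on_incomplete="keep"`).

## Calibration

The objective is the unweighted three-trait sum of squares in raw units
(μm² and μm mixed, as defined); the lumen-area term therefore dominates
numerically.  An optional per-trait weighting hook exists but is off by
default.  Minimisation uses Nelder–Mead (scipy, adaptive parameters,
`xatol 1e-8`, `fatol 1e-9`, 3000 iterations) in log-space for
positivity-constrained parameters (all kinetic constants and `c`; `a` and
`b` may be negative and are fitted raw), with 4 extra starts jittered ±10 %
from the initial point by a fixed-seed generator (42).  Invalid parameter
sets and non-terminating rings return a large penalty so the simplex steps
over them.  Observed tracheidograms must be standardized (linear
interpolation on normalized position, endpoints preserved) to the forward
model's cell count before fitting; a mismatch is an error, never an
implicit resample.

On noiseless synthetic data the curve coefficients are recovered to well
under 1 %.  Under trait noise the coefficients `a` and `b` trade off along
a sloppy ridge that the LA-dominated objective barely constrains, so
per-coefficient error is a poor yardstick at realistic ring sizes; the
package measures noisy recovery as the RMS error of the recovered model's
predicted trait profiles against the true noiseless profiles, which
decreases with ring size (0.44 % at 25 cells to 0.35 % at 100 cells under
2 % CV noise, averaged over five fixed seeds).

## Synthetic observations

`generate_synthetic_observations` overlays independent multiplicative
Gaussian noise per trait and cell, `trait·(1 + CV·z)` truncated positive,
default CV 0.02 (a stress tier at 0.10 is used in exploratory work).
Multiplicative noise keeps traits spanning two orders of magnitude
comparably perturbed and positive.  The generator emulates a mean
tracheidogram with measurement scatter only: it does not model
cell-count variation between radial files, sectioning artefacts,
row-to-row variability or multi-year rings, so passing recovery tests
demonstrate identifiability of the machinery, not field-data performance.

## Known limitations

* Environmental drivers (temperature, water) act only implicitly through
  the seasonal sugar curve; there is no explicit climate forcing, which is
  the likeliest reason the traits of the last latewood cells are the least
  well reproduced.
* Cambial division, cell–cell interaction and spatial morphogen gradients
  are out of scope; the number of cells per ring is an input, not a
  prediction.
* Final wall thickness is non-monotone in `S` at high availability (the
  occlusion regime): monotonicity assertions are restricted to
  S ∈ [0.5, 2.5].
* With the published parameter tables the model reproduces the published
  latewood percentages and marginal phase durations only approximately for
  some species; the acceptance script reports whatever the computation
  yields, and the single-cell low-sugar larch case ends by death during
  enlargement rather than at the wall-thickness threshold.
* Identifiability of the full 13-parameter refit is not established; the
  suite asserts SSE descent, with unique recovery demonstrated only for
  curve coefficients and single kinetic rates.
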