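"""Temporal dynamics of one differentiating tracheid at low vs high sugar.

Simulates a Larix decidua cell at two constant sugar availabilities and
prints the phase durations and final anatomy.  More sugar means faster wall
deposition, an earlier end of enlargement, and therefore a smaller cell with
a thicker wall — the earlywood-to-latewood contrast in miniature.
"""

from xylosim import load_fixture, phase_durations, simulate_cell

params, _ = load_fixture("Larix decidua")

for S in (1.58, 2.65):
    traj = simulate_cell(params, S)
    enlargement, thickening = phase_durations(traj)
    tr = traj.traits
    print(f"S = {S}:")
    print(f"  enlargement {enlargement:5.1f} d, wall thickening {thickening:5.1f} d")
    print(
        f"  final cell area {traj.CA[-1]:7.1f} um^2, wall thickness {tr.WT[-1]:.2f} um,"
        f" lumen radial diameter {tr.LRD[-1]:.1f} um"
    )
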