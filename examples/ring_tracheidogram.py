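"""Simulate a whole tree ring and summarise its tracheidogram.

Each of the 100 cells develops independently at the sugar availability of
its relative position; the terminal anatomies form the tracheidogram.  The
printed latewood percentage uses Mork's criterion (lumen no wider than twice
the double wall).
"""

from xylosim import latewood_percentage, load_fixture, simulate_ring

for species in ("Pinus cembra", "Picea abies", "Larix decidua", "Picea mariana"):
    params, curve = load_fixture(species)
    ring = simulate_ring(params, curve, n_cells=100)
    tr = ring.tracheidogram
    print(
        f"{species:14s}  S: {ring.S[0]:.2f}->{ring.S[-1]:.2f}  "
        f"LRD: {tr.LRD[0]:5.1f}->{tr.LRD[-1]:5.1f} um  "
        f"WT: {tr.WT[0]:.2f}->{tr.WT[-1]:.2f} um  "
        f"latewood {latewood_percentage(tr):5.1f} %"
    )
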