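"""Generate an observed-like tracheidogram with known ground truth.

Overlays 2 % multiplicative trait noise on a simulated Picea mariana ring
and writes it to CSV; the generating parameters and seed travel in the file
header, so downstream recovery experiments know their truth.
"""

from xylosim import NoiseModel, generate_synthetic_observations, load_fixture
from xylosim.io import write_tracheidogram

params, curve = load_fixture("Picea mariana")
tr = generate_synthetic_observations(params, curve, n_cells=60, noise=NoiseModel(seed=42))
write_tracheidogram(tr, "synthetic_ring.csv")

print(f"wrote synthetic_ring.csv: {tr.n_cells} cells, source={tr.metadata['source']}")
print(f"noise CVs: {tr.metadata['noise']}")
print(f"first cell: LA={tr.LA[0]:.1f} um^2, LRD={tr.LRD[0]:.1f} um, WT={tr.WT[0]:.2f} um")
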