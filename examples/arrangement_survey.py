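"""Camera-arrangement planning: survey statistics and the simulator.

Loads the packaged 125-record field survey of ground-target pixel counts
(pitch 10-50 deg x height 210-230 cm x distance 3-5 m), reports the
extreme arrangements and the resolution given up by the operating
choice, then re-simulates the whole grid with the pinhole/wide-angle
projection model and compares.
"""

import numpy as np

from agrocam.geometry import recommend_arrangement, sweep_arrangements
from agrocam.synthscene import make_table1_fixture

table = make_table1_fixture()
best = recommend_arrangement(table)
worst = recommend_arrangement(table, objective="min")
loss = 100.0 * (best.n_pixels - worst.n_pixels) / best.n_pixels
print(f"survey records: {len(table)}")
print(
    f"n_max = {best.n_pixels:,.0f} px at (alpha={best.alpha_deg:.0f} deg, "
    f"h={best.height_cm:.0f} cm, d={best.distance_m} m)"
)
print(
    f"n_min = {worst.n_pixels:,.0f} px at (alpha={worst.alpha_deg:.0f} deg, "
    f"h={worst.height_cm:.0f} cm, d={worst.distance_m} m)"
)
print(f"worst-case resolution loss: {loss:.1f} %")

chosen = table.lookup(20, 220, 4.5)
print(
    f"operating arrangement (20 deg, 220 cm): n = {chosen:,.0f} px, "
    f"giving up {100 * (best.n_pixels - chosen) / best.n_pixels:.0f} % of n_max"
)

sim = sweep_arrangements(
    [10, 20, 30, 40, 50], [210, 215, 220, 225, 230], [3.0, 3.5, 4.0, 4.5, 5.0]
)
merged = sim.records.merge(
    table.records, on=["alpha_deg", "height_cm", "distance_m"],
    suffixes=("_sim", "_meas"),
)
r = np.corrcoef(merged["n_pixels_sim"], merged["n_pixels_meas"])[0, 1]
print(f"simulated areas vs measured counts: Pearson r = {r:.3f} over 125 cells")
print("(closer targets always win; pitch 30 deg is worst at d = 3 m because")
print(" the target then sits at the image centre, where magnification is lowest)")
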