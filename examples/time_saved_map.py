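"""Map where the helicopter saves time on the way to thrombectomy.

Rasterizes the difference in onset-to-groin time between bypass by ground
and bypass by helicopter over a 10-km grid; positive cells mark where the
ground route is slower, i.e. where flying pays off.
"""

import numpy as np

import helistroke as hs

cfg = hs.ExperimentConfig(master_seed=1)
grid = hs.run_time_saved_grid(cfg)

vals = grid["values"]
inside = vals[~np.isnan(vals)]
print(f"grid: {vals.shape[1]} x {vals.shape[0]} cells of "
      f"{grid['resolution']:.0f} km")
print(f"helicopter saves time in {np.mean(inside > 0):.0%} of cells")
print(f"minutes saved: median {np.median(inside):.0f}, "
      f"max {inside.max():.0f}, min {inside.min():.0f}")
# Savings grow with distance from the comprehensive centers; negative cells
# sit next to a CSC, where driving straight in beats waiting for take-off.
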