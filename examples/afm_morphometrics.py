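"""AFM grain morphometrics on a simulated DNA + protein scene.

Renders a worm-like-chain DNA contour with a protein blob bound at 19% of
the contour, detects grains by sigma-multiplier masking and reports the
binding position as percent distance from the nearest DNA end.
"""

import numpy as np

from smquant.afm import GrainParams, dna_binding_position, filter_grains, mask_grains
from smquant.simulate import simulate_afm_scene

positions = []
for seed in range(10):
    hmap, truth = simulate_afm_scene(map_size=256, pixel_size=2.0,
                                     dna_length=115.0, persistence_length=50.0,
                                     blob_positions=[0.19], noise_sd=0.05,
                                     seed=seed)
    out = dna_binding_position(truth.polyline, truth.blob_xy[0])
    positions.append(out["pct_from_end"])
print(f"blob bound at 19% of a 115 nm dsDNA contour across 10 molecules:")
print(f"  mean recovered position = {np.mean(positions):.1f}% from the "
      "nearest end ('edge' region = outer 25% per end)")

hmap, _ = simulate_afm_scene(map_size=256, pixel_size=2.0,
                             blob_positions=[0.19], blob_height=4.0,
                             noise_sd=0.05, seed=0)
params = GrainParams(k_sigma=1.5, min_area=50.0)
grains = filter_grains(mask_grains(hmap, params), params)
print(f"sigma-multiplier masking (1.5 sigma) finds {len(grains)} grain(s); "
      f"drop counts: {grains.drop_counts}")
for g in grains.grains:
    print(f"  grain: area {g.area:.0f} nm^2, bounds "
          f"{g.min_bound:.1f} x {g.max_bound:.1f} nm, "
          f"height {g.max_height:.1f} nm")
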