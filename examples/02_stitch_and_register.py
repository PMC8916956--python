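"""Stitch a jittered multi-cycle acquisition and measure recovery error.

Cycle-1 tiles are mosaicked edge-to-edge by phase correlation on the nuclear
channel, later cycles are registered to cycle 1, and all channels are
assembled into one mosaic.  Because the input is synthetic, the recovered
origins can be compared against the generator's hidden truth.
"""

import numpy as np

from mcmini import stitchreg, synthgen

truth = synthgen.make_tissue_truth(140, (800, 800), seed=7, rim_blur_px=0.0)
acq = synthgen.render_tiles(
    truth, 3, 3, overlap=0.1, jitter_sd=3.0, cycles=2, cycle_offset=(7, 7),
    noise_sd=5.0, seed=2,
)

edges = stitchreg.align_cycle1_edges(acq, nuclear_channel="DNA")
print(f"{len(edges)} adjacent tile pairs correlated; "
      f"confidences {min(e.confidence for e in edges):.1f}"
      f"-{max(e.confidence for e in edges):.1f}")

positions = stitchreg.solve_global_positions(edges, acq, seed=0)
errs = np.array(
    [np.subtract(positions.origin(0, r, c), acq.true_origins[(0, r, c)])
     for r in range(3) for c in range(3)]
)
errs -= errs.mean(axis=0)  # a global translation is unobservable
rmse = np.sqrt((errs**2).sum(axis=1).mean())
print(f"cycle-1 origin RMSE vs truth (gauge removed): {rmse:.3f} px")

positions = stitchreg.register_cycle(acq, 1, positions)
mosaic = stitchreg.assemble_mosaic(acq, positions)
print(f"mosaic: {mosaic.data.shape[0]} channels {mosaic.channel_names}, "
      f"{mosaic.shape[0]}x{mosaic.shape[1]} px")
# RMSE well below 1 px means stitching errors will not blur single cells,
# and the (7,7) cycle offset has been absorbed into corrected coordinates.
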