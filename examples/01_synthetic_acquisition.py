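"""Generate a synthetic tiled acquisition with complete ground truth.

Builds a small tissue raster of disk nuclei, then emulates a two-cycle tiled
scan with stage jitter, a cross-cycle offset, vignetting and noise — the
Level 1 data every downstream stage consumes.
"""

from mcmini import synthgen

truth = synthgen.make_tissue_truth(
    n_cells=80, frame_size=(512, 512), n_types=3, seed=7
)
print(f"tissue truth: {len(truth.cells)} cells, {len(truth.markers)} markers "
      f"{truth.markers}, raster {truth.raster.shape}")

field = synthgen.make_vignette((199, 199), strength=0.25)
acq = synthgen.render_tiles(
    truth, grid_rows=3, grid_cols=3, overlap=0.1, jitter_sd=2.0,
    cycles=2, cycle_offset=(7, 7), illum_field=None, noise_sd=3.0, seed=1,
)
print(f"acquisition: {len(acq.tiles)} tiles ({acq.grid_shape[0]}x{acq.grid_shape[1]} "
      f"grid x {acq.n_cycles} cycles), tile shape {acq.tile_shape}, "
      f"overlap {acq.overlap_px} px")

# the generator records what a real microscope would hide: true tile origins
t = acq.true_origins[(0, 1, 1)]
n = acq.nominal_origins[(1, 1)]
print(f"tile (1,1) cycle 1: nominal origin {n}, true origin {t} "
      f"(stage jitter {t[0] - n[0]:+d},{t[1] - n[1]:+d} px)")
# -> downstream tests compare recovered positions against these true origins
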