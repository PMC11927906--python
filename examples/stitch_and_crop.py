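"""Stitch a 3x3 well montage and extract the 15 overlapping crops.

The 4x4 crop grid advances by stride floor((side - crop)/3); the
bottom-right cell is discarded, leaving 15 crops per well.
"""

from platescreen import CropGridSpec, MontageSet, MorphologyParams, PlateEffect, render_well
from platescreen.imaging import crop_grid, grid_origins, stitch_montage

tiles = render_well(0.4, MorphologyParams(), PlateEffect(), tile_size=200, seed=1)
stitched = stitch_montage(MontageSet(tiles=tiles, overlap_fraction=0.0))
print(f"9 tiles of 200 px -> stitched image {stitched.shape[0]} x {stitched.shape[1]}")

spec = CropGridSpec(crop_size=256)
origins = grid_origins(stitched.shape[0], spec)
print(f"crop origins along each axis: {origins} (stride {origins[1]})")
print(f"adjacent crops overlap by {spec.crop_size - origins[1]} px")

crops = crop_grid(stitched, spec, plate_id="P1", well_id="W1")
print(f"kept crops: {len(crops)} (bottom-right grid cell discarded)")
print("crop indices:", [c.crop_index for c in crops])
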