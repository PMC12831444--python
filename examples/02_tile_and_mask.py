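"""Otsu tissue masking and two-scale sliding-window tiling of one slide.

The same machinery that would tile a real whole-slide image: luminance
thresholding separates stained tissue from the white background, then a
non-overlapping sliding window records every tile with enough tissue.
"""

from spcl.synthetic import generate_slide, make_class_library
from spcl.tiling import compute_otsu_mask, sliding_window_tiles

slide = generate_slide(640, 640, 8, make_class_library(4, seed=0), seed=1,
                       background_border=48, slide_id="demo")
mask = compute_otsu_mask(slide.image, source_id="demo")
print(f"Otsu threshold {mask.threshold:.0f} (tissue = darker side), "
      f"tissue fraction {mask.tissue_fraction:.3f}")

# large patches feed sample-positive pretraining; small ones the classifier
for size in (64, 32):
    manifest = sliding_window_tiles(mask, tile_size=size, stride=size,
                                    min_tissue_fraction=0.9)
    print(f"{size:3d} px tiles: {len(manifest)} retained "
          f"(grid {(640 - size) // size + 1} x {(640 - size) // size + 1}, "
          f"non-overlapping)")
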