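"""Divide a camera frame into per-chamber crop rectangles.

A 1920x1080 recording of a 4x8 chamber arena is partitioned into 32 crop
rectangles; the manifest printed here is what an external video-cropping
tool consumes to split the full-frame video into per-chamber videos.
"""

from flybeam import ArenaLayout, compute_crop_grid

layout = ArenaLayout(frame_width=1920, frame_height=1080, rows=4, cols=8)
rects = compute_crop_grid(layout)

print("chamber_id,row,col,x0,y0,width,height")
for i, r in enumerate(rects[:5]):
    print(f"c{i:02d},{r.row},{r.col},{r.x0},{r.y0},{r.width},{r.height}")
print(f"... {len(rects)} rectangles in total")

# The cells tile the frame exactly: widths within a row differ by at most
# one pixel, and no two rectangles overlap.
area = sum(r.width * r.height for r in rects)
print(f"total cell area {area} px^2 == frame area {1920 * 1080} px^2")
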