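"""Score a literature-described gyne with the packaged two-character key.

The holotype gyne of the smaller thief-ant species was described only in
print: a 'head width before eyes' of 0.72 mm and a clypeal-dent distance
known solely as the ratio CLSPD/CW = 0.169 measured from the original
drawing.  The package converts both to the standard characters and evaluates
the packaged discriminant 35.24·CW − 58.91·CLSPD − 22.59 (mm units).
"""

from morphodelim import (
    clspd_from_drawing_ratio,
    cw_from_reported_head_width,
    published_keys,
    score,
)

cw = cw_from_reported_head_width(0.72, factor=1.148)
clspd = clspd_from_drawing_ratio(0.169, cw)
gyne_key = {k.name: k for k in published_keys()}["gyne_key"]
s = score(gyne_key, {"CW": cw, "CLSPD": clspd}, units="mm")

print(f"CW    = {cw:.3f} mm   (0.72 mm head width before eyes x 1.148)")
print(f"CLSPD = {clspd:.3f} mm   (drawing ratio 0.169 x CW)")
print(f"gyne key score = {s:.2f}")
lo, hi = gyne_key.class_stats["juliae"]["range"]
print(f"negative scores (range {lo} to {hi}) indicate the smaller species "
      f"(S. juliae); the holotype is firmly inside that range")
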