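"""Local fit assessment with segment-based scores (SCCC / SMI).

A two-domain toy model generates the target map; then the second domain is
deliberately displaced by 5 Å. Segment-based CCC localizes the damage: the
displaced domain's SCCC collapses while the untouched domain stays near 1.
Per-segment values are exported as a residue attribute file for coloring
the model in a molecular viewer.
"""

import numpy as np

from emscore import (
    SegmentSelection,
    make_toy_structure,
    sccc,
    simulate_map,
    smi,
    write_attributes,
)

model = make_toy_structure(30, "two-domain", hinge_angle=25.0)
target = simulate_map(model, resolution=8.0, apix=2.0)

segments = [
    SegmentSelection((("A", 1, 15),), label="domain1"),
    SegmentSelection((("A", 16, 30),), label="domain2"),
]

coords = model.coords.copy()
moved_idx = [i for i, a in enumerate(model.atoms) if a.res_seq >= 16]
coords[moved_idx] += np.array([5.0, 0.0, 0.0])
displaced = model.with_coords(coords, label="displaced")

print(f"{'segment':10s} {'SCCC(good)':>11s} {'SCCC(bad)':>11s} "
      f"{'SMI(good)':>10s} {'SMI(bad)':>10s}")
scores = {}
for seg in segments:
    row = (sccc(model, seg, target, 8.0), sccc(displaced, seg, target, 8.0),
           smi(model, seg, target, 8.0), smi(displaced, seg, target, 8.0))
    scores[seg.label] = row[1]
    print(f"{seg.label:10s} {row[0]:11.3f} {row[1]:11.3f} {row[2]:10.3f} {row[3]:10.3f}")

write_attributes(displaced, scores, segments, "segment_sccc.txt",
                 attribute_name="sccc")
print("\nwrote segment_sccc.txt (per-residue attribute file for viewer coloring)")
print("domain2's score drop pinpoints the mis-fitted region; domain1 is "
      "unaffected - exactly what a global score would average away.")
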