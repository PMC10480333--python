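"""Slide-stack bookkeeping: positions, length check, mesh cross-sections.

Builds a 10-slide stack (10 um each, two placeholder slides for removed
sections), places the slides along the cutting axis, compares the stack
length with the expected tissue length, and rasterizes the micro-CT
cross-section of the dome phantom at one slide position.
"""

import json

from aneuwall import SlideStack, length_report, slide_positions
from aneuwall.slides import Slide, slice_mesh_at_plane
from aneuwall.synthetic import generate_dome_phantom

stack = SlideStack([
    Slide(index=i, thickness_um=10.0,
          stain=None if i in (4, 9) else ["HE", "MT", "ORO", "ASMA"][i % 4],
          placeholder=i in (4, 9))
    for i in range(10)
])

positions = slide_positions(stack)
print("mid-slice positions (mm):",
      [round(p, 4) for p in positions.tolist()])

report = length_report(stack, expected_length_mm=0.11)
print(json.dumps(report, indent=2))
# A positive discrepancy of one median slide thickness suggests one
# slide was lost during preparation.

dome = generate_dome_phantom(seed=1).dome
sl = slice_mesh_at_plane(dome, offset_mm=2.0, axis_direction=(0, 0, 1),
                         px_per_mm=20.0)
print(f"cross-section at z=2 mm: {sl.mask.sum()} px, "
      f"{sl.area_mm2:.2f} mm^2")
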