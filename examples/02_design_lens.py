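"""Design a tri-curve toric lens and inspect its geometry.

Builds a -3.00 / -1.00 x 90 prescription on an 8.5 mm base curve and
reports the zone radii, per-meridian power extremes, front radii along
the principal meridians, and the thickness map statistics.
"""

import numpy as np

from onlenspower import LensDesignSpec, build_lens, get_material, zone_radii

material = get_material("H64p0-Clear")
spec = LensDesignSpec(
    diameter=14.0,
    sph=-3.0,
    cyl=-1.0,
    cyl_axis=90.0,
    refractive_index=material.refractive_index,
)
lens = build_lens(spec)

r1, r2, r3 = zone_radii(spec.base_curve)
print(f"back zone radii (optic/transient/peripheral): {r1}, {r2}, {r3} mm")
print(f"power profile: Pmax {lens.power.p_max:+.2f} D at the {spec.cyl_axis:.0f} deg "
      f"meridian, Pmin {lens.power.p_min:+.2f} D across it")
j_axis = int(spec.cyl_axis)
print(f"front radius along the axis meridian:  {lens.front_radii[j_axis]:.4f} mm")
print(f"front radius across it (0 deg):        {lens.front_radii[0]:.4f} mm")
print(f"central thickness after design: {lens.final_tc:.2f} mm")
t = lens.thickness
print(f"thickness map: min {t.min():.3f} mm, max {t.max():.3f} mm "
      f"(ballast thickens the lower half toward the edge)")
print("The steeper front radius sits on the axis meridian, which carries the "
      "maximum (least negative) power of the sphero-cylinder; thickness never "
      "drops below the 0.1 mm manufacturing floor.")
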