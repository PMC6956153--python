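"""A reduced material x power sweep with the study's statistics.

Sweeps two hydrogels over a coarse spherical power grid at one diameter,
then splits the table at 5 D, runs the pairwise t-tests and the
EPC-power correlations, and flags clinical acceptability (|EPC| <= 0.25 D).
The full-grid equivalent is `onlenspower sweep` on the command line.
"""

from onlenspower import SweepConfig, correlations, pairwise_ttests, region_split, run_sweep
from onlenspower.sweep import acceptability

config = SweepConfig(
    materials=("H77p0-Clear", "H64p0-Clear"),
    lens_types=("spherical",),
    powers=tuple(float(p) for p in range(-10, 21, 5)),
    diameters=(14.0,),
    n_meridians=180,
    n_radial=81,
)
table = acceptability(run_sweep(config))

print(table[["material", "power", "epc", "within_acceptable"]].to_string(index=False))

lower, upper = region_split(table)
print("\npairwise t-tests (lower region, power < 5 D):")
print(pairwise_ttests(lower)[["material_a", "material_b", "p_value"]].to_string(index=False))
print("\nEPC-power correlations (upper region, power >= 5 D):")
print(correlations(upper)[["material", "pearson_r"]].to_string(index=False))
print("\nEPC decreases with lens power; the strong negative correlation in "
      "the >= 5 D region mirrors the near-linear high-power decline.")
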