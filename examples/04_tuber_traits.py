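"""Morphological traits of a watertight tuber mesh.

Generates a synthetic tuber (superellipsoid with surface bumps), then
computes the seven indices used for 3D phenotyping. Lengths are bounding
box extents (cm); sphericity (36 pi V^2)^(1/3) / A and convexity
V / V_hull are both 1 for a perfect sphere / convex body and fall as the
shape elongates or dents.
"""

from pinreg3d import TuberSpec, compute_traits, generate_tuber_mesh

for label, spec in [
    ("smooth ellipsoid-like", TuberSpec(semi_axes=(55, 35, 28),
                                        bump_amplitude=0.0, seed=1)),
    ("bumpy tuber", TuberSpec(semi_axes=(55, 35, 28), bump_amplitude=2.5,
                              bump_frequency=8.0, seed=1)),
]:
    mesh = generate_tuber_mesh(spec)
    traits = compute_traits(mesh)
    print(f"{label}:")
    for key, value in traits.as_dict().items():
        print(f"  {key:>18}: {value:8.4f}")
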