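"""Cross-strip rough matching: the rotation profile and its candidates.

After the two pin frames are aligned, one degree of freedom remains — the
rotation about the pin normal. The search rotates the partial cloud in 10°
steps, finds the best small tilts about the tangents from two 1 mm
cross-strips at each step, and scores the one-way RMSD over the 3 cm pin
neighborhood. Local minima of that circular profile are the candidate
alignments; the global minimum is usually, but not always, the right one —
which is why they are ranked rather than auto-committed.
"""

from pinreg3d import (apply_transform, crop_neighborhood, init_by_pin,
                      make_fixture_pair, reference_from_swatch,
                      scan_N_rotations)
from pinreg3d.pipeline import segment_and_fit

pair = make_fixture_pair(seed=12, transform_magnitude=30.0)
ref = reference_from_swatch(pair.pin_swatch)

src_idx, src_frame = segment_and_fit(pair.partial_cloud, None,
                                     pair.pin_indices_partial)
tgt_idx, tgt_frame = segment_and_fit(pair.full_cloud, ref)

init = init_by_pin(src_frame, tgt_frame)
src_nbhd = crop_neighborhood(apply_transform(pair.partial_cloud, init),
                             tgt_frame, 30.0)
tgt_nbhd = crop_neighborhood(pair.full_cloud, tgt_frame, 30.0)
profile = scan_N_rotations(src_nbhd, tgt_nbhd, tgt_frame, init=init)

print(f"pin-only init RMSD over the neighborhood: {profile.rmsd_init:.3f} mm")
print("theta_N profile (deg -> mm):")
for angle, rmsd in zip(profile.angles_N, profile.rmsd):
    bar = "#" * int(rmsd * 30)
    print(f"  {angle:5.0f}  {rmsd:6.3f}  {bar}")
print("candidates (local minima, ranked by RMSD):")
for c in profile.candidates:
    print(f"  rank {c.rank}: theta_N={c.theta_N:5.1f}  "
          f"theta_u={c.theta_u:+.1f}  theta_v={c.theta_v:+.1f}  "
          f"rmsd={c.rmsd:.3f} mm")
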