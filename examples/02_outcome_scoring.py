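"""Score one patient's pre/post fields: improved area, MTD and responder flag.

Constructs a left hemianopic baseline (5 dB in the left hemifield, flagged
at the 0.5% TD-probability level) and a follow-up where three left-hemifield
points gained 8 dB, then scores the trial outcomes.
"""

from vftrial import RegionSpec, field_from_maps, region_members, score_patient
from vftrial.grid import common_frame_locations

common = common_frame_locations()
left = region_members(RegionSpec.hemifield("left"))

pre_sens = {loc: (5.0 if loc.x_deg < 0 else 30.0) for loc in common}
td = {loc: s - 32.0 for loc, s in pre_sens.items()}
prob = {loc: (0.5 if loc.x_deg < 0 else 100.0) for loc in common}
pre = field_from_maps("P001", "baseline", pre_sens, td=td, td_prob=prob)

post_sens = dict(pre_sens)
post_td = dict(td)
for loc in left[:3]:  # three points gain 8 dB after training
    post_sens[loc] += 8.0
    post_td[loc] += 8.0
post = field_from_maps("P001", "week12", post_sens, td=post_td, td_prob=prob)

rec = score_patient(pre, post, arm="NV")
print(f"classified defect: {rec.vfd_side} {rec.vfd_type}")
print(f"improved area, defective hemifield: {rec.improved_area_hemi_deg2:.0f} deg^2"
      f" (3 points x 36 deg^2)")
print(f"improved area, whole field:        {rec.improved_area_whole_deg2:.0f} deg^2")
print(f"MTD defective hemifield: {rec.mtd_pre_hemi:.2f} -> {rec.mtd_post_hemi:.2f} dB"
      f" (delta {rec.mtd_delta_hemi:+.2f})")
print(f"responder (hemifield): {rec.responder_hemi}")
print("\nA point counts as improved when it gains >= 6 dB from a sub-30 dB "
      "baseline; MTD is the\nregional mean total deviation, and any strictly "
      "positive MTD change marks a responder.")
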