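"""Simulate training sessions headlessly and summarise observer performance.

Runs two weeks of the NV program (peripheral stimuli, 4.3:1 toward the
defective hemifield) for a simulated hemianopic observer who gains 1 dB of
sensitivity per week at trained locations, then tabulates weekly accuracy.
"""

import numpy as np

from vftrial import (
    ObserverModel,
    RegionSpec,
    TrainingConfig,
    VfdClassification,
    performance_summary,
    region_members,
    run_program,
)
from vftrial.grid import common_frame_locations, hemifield_of

vfd = VfdClassification(
    side="left", vfd_type="hemianopia", quadrant=None,
    defect_mask=RegionSpec.mask(region_members(RegionSpec.hemifield("left"))),
)
observer = ObserverModel(
    sensitivity={
        loc: (10.0 if hemifield_of(loc) == "left" else 28.0)
        for loc in common_frame_locations()
    },
    beta=0.4, theta_db=15.0, lapse=0.02, learning_db_per_week=1.0,
)

config = TrainingConfig(weeks=2)  # scale down from the full 12-week program
log = run_program(observer, "NV", vfd, config, seed=7)
print(f"{log.sessions_completed} sessions, {len(log.records)} trials "
      f"(compliance {log.compliance:.0%})")

df = log.to_frame()
frac_def = (df["hemifield"] == "defective").mean()
print(f"placements in the defective hemifield: {frac_def:.1%} "
      f"(sampling odds 4.3:1 -> expected {4.3 / 5.3:.1%})")

summary = performance_summary(log)
for week, grp in summary.groupby("week"):
    acc = np.average(grp["accuracy"], weights=grp["n_trials"])
    print(f"week {week}: accuracy {acc:.3f} over {grp['n_trials'].sum()} trials")
print("\nAccuracy rises as the observer's trained-location sensitivity "
      "climbs the psychometric\nfunction; a static observer would stay flat.")
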