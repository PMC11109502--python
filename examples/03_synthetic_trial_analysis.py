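"""Simulate a full two-arm trial, score it, and run the statistics battery.

Generates the default synthetic cohort (40 NV / 35 NV-C completers-scale,
3 dB test-retest noise, arm-specific improvement probabilities), integrates
the exams, scores every patient with both visits, and prints the trial
report: between-arm improved-area comparison, within-arm MTD changes, and
responder percentages.
"""

from vftrial import (
    CohortConfig,
    analyze_trial,
    generate_cohort,
    integrate_cohort,
    score_patient,
)

config = CohortConfig(seed=42)
data = generate_cohort(config)
print(f"generated {len(data.truths)} patients, {len(data.exams)} exams "
      f"({int(data.meta['dropped'].sum())} dropouts)")

fields = {}
for f in integrate_cohort(data.exams):
    fields.setdefault(f.patient_id, {})[f.visit] = f

arm_of = dict(zip(data.meta["patient_id"], data.meta["arm"]))
outcomes = [
    score_patient(v["baseline"], v["week12"], arm_of[pid])
    for pid, v in sorted(fields.items())
    if len(v) == 2  # completers only
]
print(f"scored {len(outcomes)} completers\n")

report = analyze_trial(outcomes)
hemi = report["regions"]["hemifield"]
means = hemi["improved_area_mean_deg2"]
print("defective hemifield:")
print(f"  improved area: NV {means['NV']:.1f} vs NV-C {means['NV-C']:.1f} deg^2, "
      f"Mann-Whitney p = {hemi['improved_area_between']['p_formatted']}")
for arm in ("NV", "NV-C"):
    mm = hemi["mtd_mean"][arm]
    within = hemi["mtd_within"][arm]
    print(f"  {arm}: MTD {mm['pre']:.2f} -> {mm['post']:.2f} dB, "
          f"{within['test']} p = {within['p_formatted']}")
resp = hemi["responders"]
print(f"  responders: NV {resp['NV']['pct']:.1f}%, NV-C {resp['NV-C']['pct']:.1f}%")
print("\nWith the default effect model both arms improve modestly; the "
      "between-arm test is null\nwhile within-arm MTD shifts reflect each "
      "arm's programmed improvement probability.")
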