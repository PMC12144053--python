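"""Generate a synthetic sensing cohort and inspect its ground truth.

The generator emits the three raw tables a smartphone-sensing study
produces — app-foreground launches, screen on/off events, and an always-on
auxiliary sensor stream — for a cohort whose per-person usage levels,
day-to-day variability, and sensor outages are known by construction.
"""

from sm_phenotype import CohortConfig, generate_cohort

config = CohortConfig(n_participants=5, n_days=10, seed=42)
logs, truth = generate_cohort(config)

print(f"foreground launch events : {len(logs.foreground):>8,}")
print(f"screen on/off events     : {len(logs.screen):>8,}")
print(f"auxiliary sensor rows    : {len(logs.aux):>8,}")
print(f"outage episodes          : {len(truth.outages):>8,}")
print()
print("per-participant true mean daily usage (minutes / launches):")
for row in truth.participants.itertuples():
    print(f"  {row.participant_id}: {row.true_mean_daily_minutes:7.1f} min, "
          f"{row.true_mean_daily_checks:6.1f} launches")
print()
print(f"configured between-person variance fraction (duration): "
      f"{truth.between_fraction_minutes:.3f}")
# The truth object is the oracle every downstream stage is tested against:
# daily realized targets, outage schedule, and implied variance structure.
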