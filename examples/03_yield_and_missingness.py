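"""Data yield and the zero-vs-NA valid-hour rule.

Event-based sensing cannot tell "no usage" from "sensor was down" by
absence of rows alone.  Valid minutes (any sensor logged a row in a
60-second window) measure how alive the sensing app was; the valid-hour
rule then decides whether an hour with no captured usage is a true zero
or missing data.
"""

import pandas as pd

from sm_phenotype import (
    CohortConfig,
    apply_valid_hour_rule,
    generate_cohort,
    hour_bins,
    yield_summary,
)

# A small cohort with a realistic outage load (~25% downtime).
config = CohortConfig(n_participants=4, n_days=14, seed=7)
logs, truth = generate_cohort(config)

rows = pd.concat(
    [logs.foreground[["participant_id", "timestamp"]],
     logs.screen[["participant_id", "timestamp"]],
     logs.aux[["participant_id", "timestamp"]]],
    ignore_index=True,
)
bins = hour_bins(rows, config.timezone)
summary = yield_summary(bins)

print(f"enrolled participant-hours: {len(bins):,}")
print(f"study yield ratio (hour-weighted)     : {summary.study_pooled:.3f}")
print(f"study yield ratio (participant means) : {summary.study_mean_of_participants:.3f}")
for row in summary.per_participant.itertuples():
    print(f"  {row.participant_id}: {row.yield_ratio:.3f} over {row.enrolled_hours} h")

print("\nvalid-hour rule on three example hours:")
for vm, usage in ((45, 0.0), (20, 0.0), (20, 5.2)):
    status, value = apply_valid_hour_rule(vm, usage)
    print(f"  {vm:>2} valid min, {usage:>4.1f} min usage -> {status:<12} value={value}")
# With >=30 valid minutes an unused hour is a credible zero; below that,
# an unused hour is NA — usage could have happened while sensing was down.
# Captured usage always stands, whatever the yield.
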