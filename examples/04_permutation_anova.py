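"""Permutation repeated-measures ANOVA on state metrics.

Plants a condition effect (a 12x state-switching hazard during events),
computes switching frequency per subject and condition through the full
pipeline, and tests the condition effect with the mixed-design permutation
ANOVA: the event condition should switch significantly more, with no group
effect (none was planted).
"""

from leidyn import (
    AnovaSpec,
    CohortConfig,
    RunConfig,
    analyze_cohort,
    generate_cohort,
    perm_rm_anova,
)

cfg = CohortConfig(n_regions=20, n_volumes=500, n_per_group=8, k_true=3,
                   state_dwell_mean=60.0, condition_coupling=12.0,
                   event_rate=8, event_dur_mean=18.0, noise_sd=0.05, seed=31)
recordings, timelines, _ = generate_cohort(cfg)
result = analyze_cohort(recordings, timelines, RunConfig(k=3, shift_tr=0, seed=2))

sub = result.metrics[result.metrics["metric"] == "switch_freq"]
print(sub.groupby("condition")["value"].agg(["mean", "std"]).round(4))

spec = AnovaSpec(within=("condition",), n_perm=1999, seed=3)
for eff in perm_rm_anova(sub, spec):
    print(f"{eff.effect:18s} F({eff.df_num},{eff.df_den}) = {eff.F:8.3f}   "
          f"p_perm = {eff.p_perm:.4f}")
# The condition main effect is significant (events carry a 12x switch
# hazard); the group effect is not (no group difference was planted).
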