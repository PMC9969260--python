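"""Generate a synthetic voice-hearing cohort and inspect its event statistics.

Builds a scaled-down two-group cohort of band-limited BOLD recordings with
planted phase-locking states and irregular event (hallucination) episodes,
then prints how the simulated episodes compare with the design targets:
roughly 14 episodes of ~9.5 s mean duration, occupying a quarter to a third
of the scan.
"""

import numpy as np

from leidyn import CohortConfig, generate_cohort

cfg = CohortConfig(n_regions=30, n_volumes=800, n_per_group=4, k_true=4, seed=42)
recordings, timelines, truth = generate_cohort(cfg)

print(f"cohort: {len(recordings)} subjects, "
      f"{cfg.n_regions} regions x {cfg.n_volumes} volumes at TR {cfg.tr} s")
n_ep = [tl.n_episodes for tl in timelines]
occ = [tl.occupancy(cfg.scan_duration) for tl in timelines]
dur = [np.mean([b - a for a, b in tl.episodes]) for tl in timelines]
print(f"episodes per scan : mean {np.mean(n_ep):.1f} (target ~{cfg.event_rate:.0f})")
print(f"mean episode dur  : {np.mean(dur):.1f} s (target ~{cfg.event_dur_mean} s)")
print(f"scan-time occupied: {np.mean(occ):.1%} (study range ~22-33%)")

lab = truth.state_labels[0]
print(f"subject 1 planted states: {len(np.unique(lab))} states, "
      f"first transitions at volumes {np.flatnonzero(np.diff(lab))[:5] + 1}")
# Each subject's ground-truth labels let every downstream stage be scored
# by parameter recovery instead of eyeballing.
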