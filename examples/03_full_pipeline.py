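"""End-to-end run: simulate, cluster at K = 4, score against ground truth.

Generates a small noisy cohort with 4 planted states and runs the complete
pipeline — filtering, Hilbert phases, coherence eigenvectors, k-means,
condition arrays (including the 8-TR hemodynamic-shift variant) and the
four state metrics — then scores the recovered state labels against the
planted ground truth.

K is fixed to 4 here. Dunn-index selection of K (select_optimal_k) works
reliably on the clustering stage itself, but on the full Hilbert route the
band-pass smears state switches into transition eigenvectors that depress
the single-linkage Dunn numerator for finer partitions; see the methods
note. The recovery below shows the label quality the full route achieves.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from leidyn import CohortConfig, RunConfig, analyze_cohort, generate_cohort

cfg = CohortConfig(n_regions=90, n_volumes=400, n_per_group=3, k_true=4,
                   noise_sd=0.1, seed=11)
recordings, timelines, truth = generate_cohort(cfg)

run_cfg = RunConfig(k=4, n_restarts=10, dunn_subsample=2000, shift_tr=8, seed=1)
result = analyze_cohort(recordings, timelines, run_cfg)

print(f"pooled eigenvectors: {result.report['n_pooled_rows']} rows "
      f"({len(recordings)} subjects x 380 retained volumes)")
print(f"K = {result.model.k}, Dunn index of the partition: {result.model.dunn:.4f}")

planted = np.concatenate([lab[10:-10] for lab in truth.state_labels])
recovered = np.concatenate(
    [result.model.labels_for(r.subject_id) for r in recordings]
)
print(f"adjusted Rand index vs planted labels: "
      f"{adjusted_rand_score(planted, recovered):.3f}")

m = result.metrics
summary = (
    m[(m["shift"] == 0) & m["metric"].isin(["switch_freq", "dwell_time"])]
    .groupby(["metric", "condition"])["value"].mean()
)
print("\nmean state dynamics (shift 0):")
print(summary.to_string(float_format=lambda v: f"{v:.3f}"))
# dwell_time is seconds per uninterrupted visit to a state; switch_freq is
# transitions per second within the condition. An ARI above ~0.8 means the
# planted states were recovered despite noise and filter smearing.
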