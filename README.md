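# leidyn

Dynamic functional-connectivity analysis of event-locked fMRI: recurrent
**phase-locking (PL) states** from leading-eigenvector dynamics analysis
(LEiDA), condition-masked temporal state metrics, and mixed-design
permutation statistics — with a synthetic cohort generator so the whole
pipeline is testable end to end without any data download.

The package is built for studies that compare brain-state dynamics between
an event condition and rest within subjects, and between groups — the
motivating case is hallucination periods marked by button presses during
resting-state fMRI in clinical and non-clinical voice-hearers — but every
stage is generic over ROI time series and BIDS-style event timelines.

## Method

For each subject, the band-limited (0.04–0.07 Hz, zero-phase fifth-order
Butterworth) ROI signals are mapped to instantaneous phases θ(n, t) via the
Hilbert transform (edge volumes trimmed: 800 → 780). At every timepoint the
phase-coherence matrix

    dFC(n, p, t) = cos(θ(n,t) − θ(p,t))

is summarised by its leading eigenvector V1(t); eigenvectors pooled across
subjects are clustered with k-means into K PL states, K selected by the
Dunn index. Event timelines become per-volume condition arrays
(nearest-integer rounding, optional 8-TR hemodynamic shift); within each
subject's analysis window, four characteristics are extracted per
condition — switching frequency (1/s), occupancy, mean dwell time (s), and
switch probabilities including a "0" state marking the other condition —
and compared with a permutation repeated-measures ANOVA (group ×
condition × state) plus FDR-corrected pairwise permutation t-tests.

## Worked example

```python
from leidyn import CohortConfig, RunConfig, analyze_cohort, generate_cohort

cfg = CohortConfig(n_regions=90, n_volumes=400, n_per_group=3, k_true=4,
                   noise_sd=0.1, seed=11)
recordings, timelines, truth = generate_cohort(cfg)
result = analyze_cohort(recordings, timelines,
                        RunConfig(k=4, shift_tr=8, seed=1))
```

Running `python examples/03_full_pipeline.py` (the same cohort) prints:

```
pooled eigenvectors: 2280 rows (6 subjects x 380 retained volumes)
K = 4, Dunn index of the partition: 0.0922
adjusted Rand index vs planted labels: 0.878

mean state dynamics (shift 0):
metric       condition
dwell_time   event       10.036
             rest         7.815
switch_freq  event        0.015
             rest         0.015
```

An adjusted Rand index of 0.878 means the clustering recovered the four
planted phase-locking states from noisy band-limited signals; dwell times
are seconds per uninterrupted visit to a state, switching frequency is
state transitions per second within each condition. The other scripts in
`examples/` walk through cohort simulation, phase/eigenvector extraction,
the permutation ANOVA (a planted 12× switching hazard during events yields
`condition F(1,14) = 7.688, p_perm = 0.0115`), and the cohort-comparison
utilities (Yates-corrected χ²(1) = 0.49267 and 0, pooled t(40) = 1.856 from
the published group summaries).

A thin CLI wraps the same library calls:

```bash
leidyn simulate --config cohort.yaml --out cohort/ --seed 1
leidyn run --manifest cohort/manifest.tsv --out results/ --kmin 3 --kmax 15 --seed 1
leidyn stats --metrics results/metrics.tsv --metric dwell_time --n-perm 10000 --seed 1
```

## Layout

| Path | Contents |
| --- | --- |
| `src/leidyn/signal.py` | band-pass filter, Hilbert phases, trimming |
| `src/leidyn/states.py` | coherence, leading eigenvectors, k-means, Dunn, templates |
| `src/leidyn/events.py` | event rasterisation, shift, windows, masking |
| `src/leidyn/metrics.py` | the four state characteristics |
| `src/leidyn/stats.py` | permutation RM-ANOVA, post hoc tests, cohort stats |
| `src/leidyn/synthetic.py` | planted-state cohort generator |
| `src/leidyn/pipeline.py`, `io.py`, `cli.py` | orchestration, text I/O, CLI |
| `docs/methods.md` | model, parameters, numerical choices, limitations |

See `docs/methods.md` for the design decisions (eigenvector sign
convention, permutation schemes, the dwell-time/bandwidth constraint on
recoverability) and known limitations.
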