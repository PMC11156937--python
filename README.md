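# fogbench

Evaluation toolkit for wearable-sensor **freezing-of-gait (FOG)** detection.

FOG is a sudden, episodic inability to initiate or continue walking that
affects a large fraction of people with Parkinson's disease. The emerging
way to quantify it objectively is to run per-sample detectors over 3-axis
acceleration from a single lower-back sensor and summarize the output into
clinically meaningful outcomes. `fogbench` implements the full measurement
methodology around such detectors — everything except the detectors
themselves:

* **Competition scoring** — per-sample confidences for the three FOG
  classes (Start Hesitation, Turn, Walking) are scored per class with
  non-interpolated average precision
  `AP = Σ_n (R_n − R_{n−1}) · P_n`
  over descending unique score thresholds, then averaged into **mAP**.
  Samples are pooled across sessions; only samples labeled both Valid and
  Task are scored; FOG of unknown class ("notype") is excluded from
  per-class scoring.
* **Operating-point metrics** — scores are binarized at the PR-curve point
  closest to (1, 1) and reported as F1 / accuracy / precision / recall /
  specificity, per class and for the binary all-FOG case.
* **Gold-standard outcomes** — percent time frozen
  (`%TF = 100 · frozen time / evaluated time`), number of FOG episodes and
  total FOG duration per subject, from run-length episode extraction with
  optional gap-merge / minimum-duration post-processing.
* **Agreement statistics** — ICC(2,1) (two-way, absolute agreement, single
  measure) between detector estimates and expert annotation, ICC(A,k)
  (k = 6 days) for day-to-day %TF stability, F-based 95% CIs, Cohen's d.
* **Daily-living analysis** — week-long 24/7 recordings restricted to
  walking bouts ± 5 s, hourly and daily %TF profiles, median night %TF
  reference, freezer vs. non-freezer Mann–Whitney contrasts per clock
  hour, Friedman/Wilcoxon daytime-vs-night analysis, Dunn's post-hoc for
  severity groups, and the two-stage Benjamini–Krieger–Yekutieli FDR
  procedure for all multiplicity correction.
* **Synthetic data** — a semi-Markov activity/signal generator and a
  tunable simulated detector that emulate the statistical structure of the
  TLVMC FOG-prediction competition dataset (class mix, episode durations,
  akinetic fractions, hour-of-day FOG intensity), so every stage runs and
  is tested without the original recordings or trained models.
* **Freeze-index baseline** — the classical 3–8 Hz / 0.5–3 Hz band-power
  ratio as a training-free reference detector.

Intended users: researchers evaluating FOG detectors, and anyone needing a
reproducible reference implementation of these outcome measures.

## Worked example

Score a simulated detector on four synthetic protocol sessions and derive
the per-subject outcomes:

```python
import numpy as np
from fogbench import (SimConfig, generate_protocol_session, simulate_detector,
                      mean_average_precision, make_mask, operating_point_table,
                      extract_episodes, subject_summary)

cfg = SimConfig(seed=7, session_duration_s=300,
                fog_trigger_probs={"turn": 0.5, "walk": 0.25, "gait_initiation": 0.4})
sessions, submission = [], {}
for i in range(4):
    rec, labels = generate_protocol_session(cfg, subject_id="S00", session_id=f"S00_t{i}")
    sessions.append((rec, labels))
    submission[rec.session_id] = simulate_detector(
        labels, quality=2.5, boundary_jitter_s=0.5, seed=7 + i,
        sampling_rate=rec.sampling_rate)

triples = [(lab, submission[rec.session_id], make_mask(lab)) for rec, lab in sessions]
print(mean_average_precision(triples))
```

Output (quality 2.5 is a deliberately imperfect detector):

```
per-class AP: {'start_hesitation': 0.431, 'turn': 0.408, 'walking': 0.557}
mAP: 0.465
all-FOG: threshold=0.913 F1=0.509 precision=0.521 recall=0.497 specificity=0.967
truth:    %TF=6.65 episodes=23   total=79.8s
estimate: %TF=6.34 episodes=6460 total=76.1s
```

The last two lines (from `subject_summary` on the pooled label and
thresholded decision series) show a characteristic pattern: duration-based
outcomes (%TF, total duration) are robust to noisy per-sample decisions,
while the episode *count* fragments badly — the reason episode counting is
the least reliable of the three gold-standard outcomes and why
`extract_episodes` exposes `merge_gap_s` / `min_duration_s` for
sensitivity analyses.

A command-line interface mirrors the library
(`fogbench simulate | baseline | score | operate | episodes | event-table |
agree | daily | report`); try `fogbench event-table` for the benchmark
dataset's event-table totals.

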