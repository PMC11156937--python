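# Methods

This note documents the models, defaults and numerical choices behind
`fogbench`, and what its synthetic experiments do and do not demonstrate.

## Scoring and operating points

Average precision is the non-interpolated step form,
`AP = Σ_n (R_n − R_{n−1}) P_n`, computed over descending *unique* score
thresholds so tied scores share one threshold. This matches the de-facto
standard of per-sample time-series scoring on hosted competition
platforms; its exactness is established against a brute-force oracle that
enumerates every threshold explicitly (tie patterns included), not against
a published worked example, because none exists for this metric at this
granularity. mAP pools samples across sessions per class
(micro-averaging, matching how a single pooled submission is scored) and
averages the three class APs without weighting. Samples labeled FOG of
unknown class ("notype") are excluded from all three per-class
computations but count as positives in the binary all-FOG analyses: their
class is unknown, their FOG status is not.

Undefined metrics (no positives under the evaluation mask, no positive
decisions for precision) raise or are reported as undefined — never
silently coerced to 0, which would corrupt any aggregate built on top.

Operating points are selected per channel as the PR-curve point with
minimal Euclidean distance to (1, 1). Distance ties break toward higher
recall — a missed freeze is clinically costlier than a false alarm — then
toward the lower threshold; both rules are deterministic and documented
rather than left to sort order. The all-FOG score series is the
per-sample maximum over the three class channels; how the original
analyses combined class confidences into a binary score is not specified
anywhere we could follow, so the max rule is this package's documented
choice (it is monotone in every channel and threshold-compatible).

## Episodes and gold-standard outcomes

Episodes are maximal runs of true samples on a binary series; intervals
are 0-based half-open `[start, end)`, which makes durations and
concatenation plain arithmetic. `merge_gap_s` (merge runs separated by
short gaps) and `min_duration_s` (drop very short runs) both default to
0/off: the benchmark's outcomes were obtainable without post-processing,
and the knobs exist because episode *counts* — unlike %TF and total
duration — are sensitive to splitting/lumping of adjacent detections.
%TF, count and duration are always computed over masked (Valid ∧ Task,
optionally bout-restricted) time only.

When multiple class channels exceed their thresholds at one sample, class
attribution for time-share tables follows argmax over the class scores;
this rule is a package choice, enforced by requiring mutually exclusive
decision channels at the API boundary.

## Agreement statistics

ICC(2,1) is the Shrout–Fleiss two-way random-effects, absolute-agreement,
single-measure form; ICC(A,k) is the McGraw–Wong absolute-agreement
mean-of-k form with k = 6 recording days. Both are computed from the
two-way (subjects × raters, no replication) ANOVA mean squares:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

Confidence intervals use the McGraw–Wong F-distribution method (the A,k
interval by the Spearman–Brown-type transform of the A,1 bounds), and the
significance test is F = MSR/MSE on (n−1, (n−1)(k−1)) df. The estimates,
CIs and p-values agree with `pingouin.intraclass_corr` to 1e-10 (checked
in the test suite, where pingouin serves as an independent oracle — it is
never the implementation). The random- vs. mixed-effects reading of the
two-way model changes interpretation only, not the point estimate, so
both named forms are exposed and the ambiguity is noted rather than
resolved. Missing cells are rejected, not imputed: day-to-day stability
is computed over the first 6 *complete* days, mirroring how incomplete
weeks are handled in practice. Cohen's d uses the df-weighted pooled SD.

## BKY two-stage FDR

Stage 1 runs the Benjamini–Hochberg linear step-up procedure at
q′ = q/(1+q); with r₁ rejections out of m hypotheses, stage 2 reruns it
at q′·m/(m−r₁) (reject none if r₁ = 0, all if r₁ = m). The adjusted
p-value of a hypothesis is defined as the smallest q at which it is
rejected, found by bisection (50 iterations, i.e. to ~1e-15): the
rejection set grows monotonically in q because both stage thresholds do.
Equivalence with a literal, independently coded implementation of the
two-stage definition is tested over exhaustively random p-vectors, and
rejection sets also match `statsmodels`' `fdr_tsbky`.

## Rank tests

Mann–Whitney U is two-tailed, with the exact null for combined samples of
at most 10 observations without ties and the tie-corrected normal
approximation otherwise (only the test and two-tailedness are fixed by
the methodology being reproduced; the small-sample exactness rule is this
package's choice). All-tied inputs return p = 1. Wilcoxon signed-rank
uses the exact null up to 25 non-zero differences; all-zero difference
vectors return p = 1 with a logged warning. The Friedman omnibus for
daytime-vs-night uses the 16 daytime hour columns plus one column holding
each subject's median night %TF, subjects as blocks; per-hour post-hocs
are paired Wilcoxon tests against that reference, BKY-adjusted. The
severity comparison treats clock hours as blocks and the three groups'
mean hourly %TF as treatments (an unusual blocked reading of a
three-group contrast, implemented as specified upstream rather than
substituting Kruskal–Wallis), followed by pairwise Dunn mean-rank
comparisons `z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/6n)` with BKY adjustment.

## Daily-living profiles

Hourly %TF is 100 × (FOG ∧ bout time)/(bout time) per clock hour, with
bouts padded by 5 s on each side under the assumption that FOG occurs
only during or adjacent to gait. Hour bins follow the local clock from
the recording's start time; each sample is attributed to the bin
containing its midpoint, which splits episodes spanning bin edges
pro-rata. A bin with zero bout time is undefined (NaN), propagated and
never imputed; week averages use only days where the bin is defined.
Daytime is 07:00–22:59 and night its complement 23:00–06:59
(configurable; only the daytime window is fixed upstream). The identity
"daily %TF = bout-time-weighted mean of defined hourly %TF" holds to
1e-9 and is tested. Ensemble decisions are the pointwise OR of member
decision series, each member binarized at its own operating point.

## Synthetic generator

The generator exists to exercise and validate the measurement pipeline,
not to imitate patients. Activity is a semi-Markov chain over
{rest, stand, gait initiation, walk, turn} with log-normal dwell times
(explicit dwell control makes episode/bout duration statistics directly
configurable, which a per-sample Markov chain would not). FOG episodes
are injected only within their triggering context; log-normal durations
with class means of ~9.7 s (turn), ~15 s (start hesitation) and ~5.7 s
(walking) follow the benchmark dataset's event-count/duration tables
(e.g. 469.1 min over 2887 turn events). The log-normal family itself is
a modeling choice — no real-world episode-duration distribution is
published — with parameters exposed. Akinetic fractions default to 5.6%
(lab dialect) and 29.3% (home dialect). The signal model is deliberately
spectral, not biomechanical: walking is a step-frequency (1.8 Hz)
fundamental plus first harmonic, trembling FOG is band-limited noise in
the 3–8 Hz freeze band, akinetic FOG and rest sit at the noise floor,
with envelope crossfading (0.3 s) for continuity and gravity on the
vertical axis. Consequently, passing tests demonstrate correctness of
the *measurement* chain under controlled conditions; they say nothing
about detector performance on real acceleration, where artifacts,
sensor misplacement and inter-subject variability dominate.

Week-long recordings place walking bouts per clock hour (5/h daytime,
0.5/h at night — sparse short "bathroom-walk" bouts keep the nocturnal
reference %TF well-defined) and scale FOG triggering by a 24-bin
hour-of-day intensity profile whose freezer default peaks at 07:00 and
22:00. Each subject carries a latent FOG-propensity multiplier drawn
from a unit-mean gamma distribution (shape 0.3). The gamma family was
chosen over a log-normal because the cohort-level standardized group
difference depends on the *sample* coefficient of variation at n = 45,
which a heavy-tailed log-normal systematically under-realizes; shape 0.3
makes the realized freezer vs. non-freezer daily-%TF Cohen's d ≈ 0.7 (a
moderate effect) at cohort sizes 45/19. Severity questionnaire scores in
the cohort manifest are rank-matched to the propensity (center 20,
spread 4, clipped to 10–28), so a median split at 20 yields genuinely
ordered moderate/severe subgroups. Non-freezers emit zero true FOG. All
randomness derives from (seed, subject id, day) streams, so cohorts are
reproducible under parallel generation.

The simulated detector maps a label series to per-class confidences
`logistic(quality · indicator + N(0,1))` after jittering episode
boundaries and inserting false-positive bursts; quality 0 is
uninformative (AP ≈ class prevalence), large quality approaches perfect
ranking, and AP/F1 increase monotonically in between — the property the
evaluation stack must preserve.

## Freeze-index baseline

FI = (3–8 Hz power)/(0.5–3 Hz power) over a centered 4 s window:
magnitude-squared FFT of the linearly detrended, Hann-windowed segment,
band power by bin summation with half-weight boundary bins (the exact
estimator is not fixed by prior art, so a deterministic, simple one is
stated). Edges are reflection-padded; windows with numerically zero
locomotor power are capped at a configured maximum (default 100) and
flagged. FI is scale-invariant by construction. `baseline_scores`
min-max scales FI to [0, 1] and replicates it to all three class
channels: the baseline has no context model, so class attribution is
left downstream.

## Problem sizes and runtime choices

Cohort experiments generate label series at 0.5–1 Hz rather than the
sensor's native 100 Hz: every outcome in the daily-living chain is a
duration ratio or rank statistic, invariant to sampling rate, and the
coarser grid keeps a 64-subject × 7-day × 20-seed recovery experiment in
the minutes range. Waveform synthesis is switched off
(`synthesize_acc=False`) wherever only labels are analyzed. Protocol
sessions for scoring tests are 300 s at the native 128 Hz. The
end-to-end recovery experiment fixes 20 seeds and asserts distributional
properties (≥ 90% of runs recover both peaks within ±1 h; mean Cohen's d
within ±0.2 of 0.7; all day-to-day ICCs above 0.9).

## Known limitations

* The generator's signal realism is minimal; no attempt is made to model
  shuffling-step kinematics, sensor noise spectra or posture transitions.
* Walking-bout *detection* from raw acceleration is out of scope; the
  daily-living pipeline consumes bout annotations (the generator emits
  ground truth), and the freeze-index baseline is a reference point, not
  a competitive detector.
* The competition's published headline numbers (mAP of the winning
  models, their Table-style metric values, their ICCs against experts)
  depend on hidden test recordings and trained model weights and are not
  reproducible here; what is reproduced is the measurement methodology
  and the dataset's published arithmetic.
* Submission Id scheme and the home-dialect acceleration units are not
  fixed by any public specification; defaults (`<session>_<sample>`,
  units of g with a configurable 9.80665 m/s² constant) are recorded in
  each recording's provenance field.
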